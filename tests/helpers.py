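"""Shared helpers for the test suite."""

import pandas as pd


def make_meta(samples, clades, populations=None, lat=24.0, lon=-100.0):
    """Minimal valid sample-metadata frame, indexed by sample id."""
    df = pd.DataFrame(
        {
            "sample": samples,
            "clade": clades,
            "population": populations if populations is not None else clades,
            "latitude": lat,
            "longitude": lon,
        }
    )
    return df.set_index("sample", drop=False)
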