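"""Embedded cohort data: the per-breast cluster table.

The table lists, for each of 30 patients (numbered 1-33 with 10, 15
and 22 absent) and each mammographic view (CC, MLO), the cluster
statistics of uncorrelated H = 0.5 ("yellow") squares in the cancerous
breast (CB) and contralateral unaffected breast (CUB): total count,
number of clusters, and the sorted cluster sizes (edge-or-corner
connectivity).  A SHA-256 checksum guards the transcription.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["table1_clusters", "table1_fixture"]

_TABLE1_SHA256 = "a8c863b7155aad704cf0d2e943448c763db9d892e880480ae2e8cdcce87ba6d0"


def _table1_bytes() -> bytes:
    return resources.files("mfscreen.data").joinpath("table1_clusters.csv").read_bytes()


def table1_clusters(verify: bool = True) -> pd.DataFrame:
    """The cohort cluster table as a tidy DataFrame.

    Columns: patient (int), view ('CC'|'MLO'), side ('CB'|'CUB'),
    total (int), n_clusters (int), sizes (list of int, descending).
    120 rows (30 patients x 2 views x 2 sides).
    """
    raw = _table1_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise RuntimeError(
                f"cluster-table fixture corrupted: sha256 {digest} != {_TABLE1_SHA256}"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), keep_default_na=False)
    df["sizes"] = df["sizes"].apply(
        lambda s: [int(v) for v in str(s).split()] if str(s).strip() else []
    )
    bad = df[
        (df["total"] != df["sizes"].apply(sum))
        | (df["n_clusters"] != df["sizes"].apply(len))
    ]
    if len(bad):
        raise RuntimeError(f"inconsistent fixture rows: {bad}")
    return df


def table1_fixture(verify: bool = True) -> pd.DataFrame:
    """Alias of :func:`table1_clusters`."""
    return table1_clusters(verify=verify)
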