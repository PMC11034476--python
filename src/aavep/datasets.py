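"""Bundled reference datasets.

Currently a single panel: 30 assay-characterized missense variants of the
human creatine transporter SLC6A8, each carrying four label columns —
the database-reported pathogenicity, the functional-assay interpretation
(the ground truth for external evaluation), the call of a combined
external variant-effect meta-predictor, and the call of a four-model
minority-rule consensus. Used for metric cross-checks and as the template
for external-evaluation audits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_slc6a8_panel"]

_BINARY = {"Benign": 0, "Pathogenic": 1}


def load_slc6a8_panel(binary: bool = False) -> pd.DataFrame:
    """The 30-variant SLC6A8 external panel, indexed by variant id.

    With ``binary=True`` the interpreted/combined_vep/consensus_model
    columns are recoded to 0/1 (pathogenic = 1); the ``reported`` column
    keeps its ``Unknown`` entries and is never recoded.
    """
    with resources.files("aavep.data").joinpath("slc6a8_external_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="id")
    if binary:
        for col in ("interpreted", "combined_vep", "consensus_model"):
            df[col] = df[col].map(_BINARY)
    return df
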