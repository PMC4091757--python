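"""Bundled reference datasets.

``hdmac_presence.tsv`` is the published 56-row presence/absence matrix
of human disease-associated mature miRNAs across the five domestic
animal species (cow, chicken, pig, horse, dog), with the curated family
label and the printed per-row species total. It serves as a desk-scale
worked example for the presence-matrix operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .homolog_match import PresenceMatrix

SPECIES_COLUMNS = ["bta", "gga", "ssc", "eca", "cfa"]


def load_hdmac_presence_frame() -> pd.DataFrame:
    """The raw curated table: +/- cells, family and printed totals."""
    ref = resources.files("mircons.data") / "hdmac_presence.tsv"
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t", index_col=0, dtype=str)


def load_hdmac_presence_matrix() -> PresenceMatrix:
    """The curated table as a boolean :class:`PresenceMatrix`."""
    df = load_hdmac_presence_frame()
    return PresenceMatrix((df[SPECIES_COLUMNS] == "+"))
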