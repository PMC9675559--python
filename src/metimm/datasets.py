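"""Loaders for the signature fixtures packaged with metimm.

Every file under ``metimm/data`` is a clearly labelled *synthetic stand-in*:
the gene symbols are plausible members of the public panels each file
emulates (hallmark metabolic sets, the 18-gene T-cell-inflamed panel, the
29-signature immune panel, stromal/immune purity signatures, ferroptosis
driver/suppressor lists, an ICI-statin study table), but the exact lists and
weighting coefficients are reconstructions curated for offline testing —
they are NOT the original published lists.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import GeneSet, SignatureCollection, StudyEffect, WeightedGeneSet, read_gmt, read_meta_table

__all__ = [
    "load_tcell_inflamed_signature",
    "load_metabolic_candidates",
    "load_immune_signatures",
    "load_estimate_signatures",
    "load_ferroptosis_signatures",
    "load_example_meta_table",
]

_DATA = resources.files("metimm") / "data"


def _data_path(name: str):
    return _DATA / name


def load_tcell_inflamed_signature() -> WeightedGeneSet:
    """The packaged 18-gene T-cell-inflamed (GEP) weighted signature.

    Synthetic stand-in weights; see module docstring.
    """
    with resources.as_file(_data_path("synthetic_tcell_inflamed_18.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    return WeightedGeneSet(
        "T_CELL_INFLAMED_18",
        tuple(table["gene"]),
        tuple(table["weight"].astype(float)),
    )


def load_metabolic_candidates() -> SignatureCollection:
    """Glycolysis / cholesterol-biosynthesis candidate gene sets (stand-ins)."""
    with resources.as_file(_data_path("synthetic_hallmark_metabolic.gmt")) as path:
        return read_gmt(path)


def load_immune_signatures() -> SignatureCollection:
    """The 29 immune cell / immune pathway signatures (stand-ins)."""
    with resources.as_file(_data_path("synthetic_immune_signatures_29.gmt")) as path:
        return read_gmt(path)


def load_estimate_signatures() -> tuple[GeneSet, GeneSet]:
    """(stromal, immune) purity signatures (stand-ins)."""
    with resources.as_file(_data_path("synthetic_estimate_signatures.gmt")) as path:
        collection = read_gmt(path)
    return collection["ESTIMATE_STROMAL"], collection["ESTIMATE_IMMUNE"]


def load_ferroptosis_signatures() -> tuple[GeneSet, GeneSet]:
    """(driver, suppressor) ferroptosis gene lists (stand-ins)."""
    with resources.as_file(_data_path("synthetic_ferroptosis.gmt")) as path:
        collection = read_gmt(path)
    return collection["FERROPTOSIS_DRIVER"], collection["FERROPTOSIS_SUPPRESSOR"]


def load_example_meta_table() -> list[StudyEffect]:
    """Synthetic stand-in for the pan-cancer ICI-statin study table.

    Six pan-cancer studies (2,135 participants) plus one in-house cohort
    (101 participants); effect sizes are invented, the enrollment totals
    mirror the scale of the analysis the table emulates.
    """
    with resources.as_file(_data_path("synthetic_ici_statin_meta.csv")) as path:
        return read_meta_table(path)
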