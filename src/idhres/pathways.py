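"""Gene-to-pathway grouping used for relapse-event and covariate summaries.

The default map groups recurrently mutated AML genes into functional
pathways: hematopoietic differentiation transcription factors, RAS-RTK
signaling, chromatin structure, DNA methylation, cohesin, and splicing.
Genes outside the map fall back to ``"other"``. The map is a total function
over gene symbols and can be loaded from / saved to an editable TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

HEMATOPOIETIC_TF = "hematopoietic_TF"
RAS_RTK = "RAS_RTK"
CHROMATIN = "chromatin"
DNA_METHYLATION = "DNA_methylation"
COHESIN = "cohesin"
SPLICING = "splicing"
OTHER = "other"

PATHWAYS = (
    HEMATOPOIETIC_TF,
    RAS_RTK,
    CHROMATIN,
    DNA_METHYLATION,
    COHESIN,
    SPLICING,
    OTHER,
)

#: Default gene grouping. Editable; ``PathwayMap.from_tsv`` overrides it.
DEFAULT_PATHWAYS: dict[str, str] = {
    # hematopoietic differentiation transcription factors
    "RUNX1": HEMATOPOIETIC_TF,
    "CEBPA": HEMATOPOIETIC_TF,
    "GATA2": HEMATOPOIETIC_TF,
    # RAS-RTK signaling
    "NRAS": RAS_RTK,
    "KRAS": RAS_RTK,
    "PTPN11": RAS_RTK,
    "NF1": RAS_RTK,
    "CBL": RAS_RTK,
    "FLT3": RAS_RTK,
    "KIT": RAS_RTK,
    # chromatin structure
    "ASXL1": CHROMATIN,
    "BCOR": CHROMATIN,
    "BCORL1": CHROMATIN,
    "EZH2": CHROMATIN,
    "KMT2A": CHROMATIN,
    "KDM6A": CHROMATIN,
    "PHF6": CHROMATIN,
    # DNA methylation
    "DNMT3A": DNA_METHYLATION,
    "TET2": DNA_METHYLATION,
    "IDH1": DNA_METHYLATION,
    "IDH2": DNA_METHYLATION,
    # cohesin
    "STAG2": COHESIN,
    "SMC1A": COHESIN,
    "SMC3": COHESIN,
    "RAD21": COHESIN,
    # splicing
    "SRSF2": SPLICING,
    "U2AF1": SPLICING,
    "SF3B1": SPLICING,
    "ZRSR2": SPLICING,
}


class PathwayMap:
    """Total gene → pathway mapping with an explicit ``"other"`` fallback."""

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map = dict(DEFAULT_PATHWAYS if mapping is None else mapping)
        bad = set(self._map.values()) - set(PATHWAYS)
        if bad:
            raise ValueError(f"unknown pathway labels: {sorted(bad)}")

    def __getitem__(self, gene: str) -> str:
        return self._map.get(gene, OTHER)

    def get(self, gene: str) -> str:
        return self[gene]

    def genes(self, pathway: str) -> list[str]:
        return sorted(g for g, p in self._map.items() if p == pathway)

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["gene"], df["pathway"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._map.items()), columns=["gene", "pathway"]
        ).to_csv(path, sep="\t", index=False)
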