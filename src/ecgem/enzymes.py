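"""Enzyme kinetic and proteomic records, unit conversions, and the packaged
central-carbon enzyme table for *B. subtilis*.

Units used throughout:

* kcat — turnover number, s⁻¹ (converted to h⁻¹ only inside the model builder)
* molecular weight — kDa, treated as exactly g/mmol (= mg/µmol)
* enzyme abundance — mmol/gDW
* specific activity (SA) — µmol product · mg enzyme⁻¹ · min⁻¹

The packaged table (``load_enzyme_table("table1")``) holds the 17 curated
central-carbon reactions with their kcat values and upper-95%-CI proteomic
abundances; two enzymes (YqiQ, MenD) were below the proteomic detection limit
and carry the dataset-minimum fallback abundance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AVOGADRO",
    "EnzymeEntry",
    "ProteomicsRecord",
    "sa_to_kcat",
    "cell_to_gdw",
    "gdw_to_cell",
    "resolve_abundance",
    "load_enzyme_table",
    "enzyme_table_frame",
    "DEFAULT_ABUNDANCE_FLOOR",
    "CELLS_PER_ML_OD",
    "GDW_PER_L_OD",
]

AVOGADRO = 6.02214076e23
#: cell density per OD600 unit (cells/mL/OD) used to convert molecules/cell
CELLS_PER_ML_OD = 6.3e8
#: biomass density per OD600 unit (gDW/L/OD)
GDW_PER_L_OD = 0.48
#: minimum measured proteomic abundance (mmol/gDW), used for undetected enzymes
DEFAULT_ABUNDANCE_FLOOR = 6.8e-8


@dataclass
class EnzymeEntry:
    """One enzyme-constrained reaction: kinetics plus proteomic abundance."""

    reaction_id: str
    gene: str
    kcat: float  # s^-1
    abundance: float  # mmol/gDW
    ec_number: str = ""
    mw: float | None = None  # kDa; required only for the total-pool constraint
    abundance_is_fallback: bool = False
    kcat_organism: str = ""

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValueError(f"{self.reaction_id}: kcat must be positive, got {self.kcat}")
        if self.abundance <= 0:
            raise ValueError(
                f"{self.reaction_id}: abundance must be positive, got {self.abundance}"
            )
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.reaction_id}: mw must be positive, got {self.mw}")


@dataclass
class ProteomicsRecord:
    """Absolute protein quantification in molecules per cell with its 95% CI
    upper limit."""

    gene: str
    mean_abundance: float
    ci95_upper: float

    def __post_init__(self) -> None:
        if not (self.ci95_upper >= self.mean_abundance >= 0):
            raise ValueError(
                f"{self.gene}: need ci95_upper >= mean_abundance >= 0, got "
                f"{self.ci95_upper} / {self.mean_abundance}"
            )


@dataclass
class ProteomicsRecords:
    records: dict[str, ProteomicsRecord] = field(default_factory=dict)

    def add(self, rec: ProteomicsRecord) -> None:
        self.records[rec.gene] = rec

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __len__(self) -> int:
        return len(self.records)


def sa_to_kcat(sa: float, mw: float) -> float:
    """Convert specific activity (µmol/mg/min) to a turnover number (s⁻¹).

    kcat = SA × MW / 60, with MW in kDa ≡ mg/µmol, assuming a pure enzyme
    preparation with one active site per subunit.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if sa < 0:
        raise ValueError(f"specific activity must be non-negative, got {sa}")
    return sa * mw / 60.0


def cell_to_gdw(
    abundance: float,
    cells_per_ml_od: float = CELLS_PER_ML_OD,
    gdw_per_l_od: float = GDW_PER_L_OD,
) -> float:
    """Convert molecules/cell to mmol/gDW.

    molecules/cell × (cells/mL/OD) / (gDW/mL/OD) gives molecules per gDW,
    which Avogadro's number turns into mol/gDW and ×1000 into mmol/gDW.
    """
    if cells_per_ml_od <= 0 or gdw_per_l_od <= 0:
        raise ValueError("conversion factors must be positive")
    if abundance < 0:
        raise ValueError(f"abundance must be non-negative, got {abundance}")
    gdw_per_ml_od = gdw_per_l_od / 1000.0
    return abundance * cells_per_ml_od / gdw_per_ml_od / AVOGADRO * 1000.0


def gdw_to_cell(
    abundance_mmol_gdw: float,
    cells_per_ml_od: float = CELLS_PER_ML_OD,
    gdw_per_l_od: float = GDW_PER_L_OD,
) -> float:
    """Inverse of :func:`cell_to_gdw` (mmol/gDW back to molecules/cell)."""
    if cells_per_ml_od <= 0 or gdw_per_l_od <= 0:
        raise ValueError("conversion factors must be positive")
    gdw_per_ml_od = gdw_per_l_od / 1000.0
    return abundance_mmol_gdw / 1000.0 * AVOGADRO * gdw_per_ml_od / cells_per_ml_od


def resolve_abundance(
    records: ProteomicsRecords,
    gene: str,
    floor: float = DEFAULT_ABUNDANCE_FLOOR,
) -> tuple[float, bool]:
    """Resolve a gene's enzyme abundance in mmol/gDW.

    When the gene was quantified, the upper limit of the 95% confidence
    interval is used (a deliberately permissive cap, so as not to
    over-constrain fluxes).  When it was not detected, the stated floor — by
    default the minimum abundance measured in the whole dataset — is
    substituted and flagged.

    Returns ``(abundance_mmol_gdw, is_fallback)``.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if gene in records:
        return cell_to_gdw(records.records[gene].ci95_upper), False
    return floor, True


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["reaction_id", "gene", "kcat_per_s", "abundance_mmol_gdw"]


def enzyme_table_frame(path_or_builtin: str = "table1") -> pd.DataFrame:
    if path_or_builtin == "table1":
        src = importlib.resources.files("ecgem.data").joinpath("table1.tsv")
        with importlib.resources.as_file(src) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path_or_builtin, sep="\t")


def load_enzyme_table(path_or_builtin: str = "table1") -> list[EnzymeEntry]:
    """Load an enzyme table (TSV) or the builtin curated table ("table1").

    Required columns: reaction_id, gene, kcat_per_s, abundance_mmol_gdw.
    Optional: ec, mw_kda, abundance_source ("detection_floor" marks fallback
    abundances), kcat_organism.
    """
    df = enzyme_table_frame(path_or_builtin)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path_or_builtin}: enzyme table lacks columns {missing}")
    entries: list[EnzymeEntry] = []
    for idx, row in df.iterrows():
        try:
            mw = row.get("mw_kda")
            mw = None if pd.isna(mw) else float(mw)
            entries.append(
                EnzymeEntry(
                    reaction_id=str(row["reaction_id"]),
                    gene=str(row["gene"]),
                    kcat=float(row["kcat_per_s"]),
                    abundance=float(row["abundance_mmol_gdw"]),
                    ec_number="" if pd.isna(row.get("ec")) else str(row.get("ec")),
                    mw=mw,
                    abundance_is_fallback=(
                        str(row.get("abundance_source", "")) == "detection_floor"
                    ),
                    kcat_organism=""
                    if pd.isna(row.get("kcat_organism"))
                    else str(row.get("kcat_organism")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"{path_or_builtin}: bad enzyme-table row {idx + 2} "
                f"(reaction {row.get('reaction_id')!r}): {exc}"
            ) from exc
    return entries
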