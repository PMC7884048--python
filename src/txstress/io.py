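"""Table I/O, configuration and diet-arithmetic utilities.

Fixed column dialects (headers mandatory, UTF-8, '.' decimal):

* expression TSV — first column ``gene_id``, remaining columns one per
  sample (linear intensities);
* design CSV — ``sample_id,group,sex``;
* survival CSV — ``animal_id,group,sex,time_weeks,event`` (event in {0,1});
* weight CSV (long) — ``animal_id,group,week,weight_g``;
* annotation — two-column TSV ``gene_id,length_bp`` or a GTF, from which
  gene lengths are genomic spans (max end - min start + 1 over a gene's
  records, 1-based inclusive).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GeneCatalog

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_survival",
    "write_survival",
    "read_weights",
    "write_weights",
    "read_annotation_tsv",
    "read_annotation_gtf",
    "load_config",
    "DietSpec",
    "diet_ppm",
    "dr_ration",
]


# ---------------------------------------------------------------------------
# Expression / design / survival / weight tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples matrix from TSV (first column = gene_id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be named 'gene_id'")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]][0]
        raise ValueError(f"{path}: non-numeric cells in column {bad!r}")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError(f"{path}: expression values must be finite and >= 0")
    return frame


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def _read_csv_with_columns(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return frame[list(columns)]


def read_design(path: str | Path) -> pd.DataFrame:
    frame = _read_csv_with_columns(path, ("sample_id", "group", "sex"))
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return frame


def write_design(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    frame = _read_csv_with_columns(
        path, ("animal_id", "group", "sex", "time_weeks", "event")
    )
    bad = ~frame["event"].isin([0, 1])
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"{path}: row {row + 2}: event must be 0 or 1, got {frame['event'].iloc[row]!r}"
        )
    if (frame["time_weeks"] < 0).any():
        raise ValueError(f"{path}: negative time_weeks")
    if frame["animal_id"].duplicated().any():
        dup = frame.loc[frame["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValueError(f"{path}: duplicate animal_id {dup!r}")
    return frame


def write_survival(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_weights(path: str | Path) -> pd.DataFrame:
    frame = _read_csv_with_columns(path, ("animal_id", "group", "week", "weight_g"))
    if (frame["weight_g"] <= 0).any():
        row = int(np.nonzero((frame["weight_g"] <= 0).to_numpy())[0][0])
        raise ValueError(f"{path}: row {row + 2}: weight_g must be > 0")
    if frame.duplicated(["animal_id", "week"]).any():
        raise ValueError(f"{path}: duplicate animal-week record")
    return frame


def write_weights(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene-length annotation
# ---------------------------------------------------------------------------


def read_annotation_tsv(path: str | Path) -> GeneCatalog:
    """Two-column TSV (gene_id, length_bp) -> GeneCatalog."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return GeneCatalog(
        frame["gene_id"].to_numpy(dtype=object), frame["length_bp"].to_numpy()
    )


def read_annotation_gtf(path: str | Path) -> GeneCatalog:
    """Genomic span lengths per gene_id from a GTF file.

    A gene's length is ``max(end) - min(start) + 1`` over all of its
    records (GTF coordinates are 1-based inclusive).  Users preferring
    transcript lengths can supply them via the two-column TSV instead.
    """
    import gffutils

    spans: dict[str, tuple[int, int]] = {}
    for feature in gffutils.DataIterator(str(path)):
        gene_ids = feature.attributes.get("gene_id")
        if not gene_ids:
            continue
        gid = gene_ids[0]
        lo, hi = spans.get(gid, (feature.start, feature.end))
        spans[gid] = (min(lo, feature.start), max(hi, feature.end))
    if not spans:
        raise ValueError(f"{path}: no records with a gene_id attribute")
    ids = np.array(sorted(spans), dtype=object)
    lengths = np.array([spans[g][1] - spans[g][0] + 1 for g in ids], dtype=np.int64)
    return GeneCatalog(ids, lengths)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

KNOWN_STAGES = (
    "simulate",
    "degs",
    "length_bias",
    "estimate_lambda",
    "pca",
    "survival",
    "auc",
    "stereology",
    "diet",
)


def load_config(path: str | Path) -> dict:
    """YAML run configuration with per-stage namespaces.

    Top-level keys must be stage names (plus optional ``seed`` and
    ``log_level``); unknown keys are rejected so typos fail loudly.
    """
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    allowed = set(KNOWN_STAGES) | {"seed", "log_level"}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return config


# ---------------------------------------------------------------------------
# Diet arithmetic
# ---------------------------------------------------------------------------


class DietSpec:
    """Dosing arithmetic for encapsulated-drug and restricted diets.

    ``encapsulated_mg_per_kg`` mg of microencapsulated compound added per kg
    food, of which ``active_fraction`` is active drug; ``adlib_intake_g_per_day``
    is the ad libitum daily intake and ``restriction_fraction`` the fractional
    ration reduction of dietary restriction.
    """

    def __init__(
        self,
        encapsulated_mg_per_kg: float = 0.0,
        active_fraction: float = 0.1,
        adlib_intake_g_per_day: float = 2.3,
        restriction_fraction: float = 0.0,
    ) -> None:
        if encapsulated_mg_per_kg < 0:
            raise ValueError("encapsulated_mg_per_kg must be >= 0")
        if not 0.0 <= active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if adlib_intake_g_per_day <= 0:
            raise ValueError("adlib_intake_g_per_day must be > 0")
        if not 0.0 <= restriction_fraction < 1.0:
            raise ValueError("restriction_fraction must be in [0, 1)")
        self.encapsulated_mg_per_kg = encapsulated_mg_per_kg
        self.active_fraction = active_fraction
        self.adlib_intake_g_per_day = adlib_intake_g_per_day
        self.restriction_fraction = restriction_fraction


def diet_ppm(spec: DietSpec) -> float:
    """Active compound in food, ppm (mg active per kg food)."""
    return spec.encapsulated_mg_per_kg * spec.active_fraction


def dr_ration(spec: DietSpec) -> float:
    """Restricted daily ration in g/day, rounded half-up to one decimal."""
    ration = Decimal(str(spec.adlib_intake_g_per_day)) * (
        Decimal(1) - Decimal(str(spec.restriction_fraction))
    )
    return float(ration.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
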