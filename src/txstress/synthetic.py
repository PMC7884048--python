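"""Synthetic data generators for the full intervention-study pipeline.

This module emulates every input the downstream analyses consume:

* a gene catalog with log-normal transcribed lengths (mimicking the mammalian
  gene-length distribution),
* expression matrices under a stochastic transcription-blocking lesion model,
* Gompertz lifespans with administrative censoring,
* sigmoid growth-then-decline weekly body-weight trajectories coupled to the
  simulated death times,
* homogeneous 3D point clouds of cell nuclei in a sectioned tissue slab.

The lesion model formalises the idea that transcription-blocking DNA damage
accumulates stochastically along a gene, so the chance that at least one
lesion stalls RNA polymerase II grows with gene length.  Lesions are Poisson
with rate ``lambda_per_kb`` per kilobase; a transcript is abolished by one or
more lesions, so the mean expression of a gene of length ``L`` kb is
multiplied by ``exp(-lambda * L)``.  Larger genes therefore lose expression
preferentially — the "transcription stress" signature the detection module
looks for.

Every generator is deterministic given its seed and returns a truth record
where the downstream analysis needs one.  Random streams are derived from
``numpy.random.SeedSequence`` with fixed spawn keys so that, e.g., adding a
group never reshuffles another group's noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCatalog",
    "LesionModelParams",
    "GompertzParams",
    "SurvivalParams",
    "GrowthSpec",
    "WeightParams",
    "TissueVolume",
    "simulate_gene_catalog",
    "simulate_expression",
    "simulate_survival",
    "simulate_weights",
    "simulate_tissue",
    "default_group_params",
    "DEFAULT_GROUPS",
]

_LN2 = np.log(2.0)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Derive a named substream from a master seed.

    Every operation draws from ``SeedSequence(seed, spawn_key=...)`` with a
    fixed per-operation key, so streams are independent and stable.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _label_key(label: str) -> int:
    """Stable 32-bit key for a group label (CRC-32)."""
    return zlib.crc32(label.encode("utf-8"))


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCatalog:
    """Gene identifiers with transcribed lengths in base pairs.

    The catalog is the backbone of both the lesion model (lesion exposure is
    proportional to length) and the length-bias statistic.
    """

    gene_ids: np.ndarray
    length_bp: np.ndarray

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        length_bp = np.asarray(self.length_bp, dtype=np.int64)
        if gene_ids.size == 0:
            raise ValueError("gene catalog must be non-empty")
        if gene_ids.size != length_bp.size:
            raise ValueError("gene_ids and length_bp must have equal length")
        if len(set(gene_ids.tolist())) != gene_ids.size:
            raise ValueError("gene_ids must be unique")
        if np.any(length_bp < 1):
            raise ValueError("gene lengths must be >= 1 bp")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "length_bp", length_bp)

    def __len__(self) -> int:
        return int(self.gene_ids.size)

    @property
    def length_kb(self) -> np.ndarray:
        return self.length_bp / 1000.0

    def lengths_for(self, ids: Sequence[str]) -> np.ndarray:
        """Lengths (bp) for the given gene ids; KeyError on unknown id."""
        table = dict(zip(self.gene_ids.tolist(), self.length_bp.tolist()))
        try:
            return np.array([table[i] for i in ids], dtype=np.int64)
        except KeyError as exc:  # re-raise naming the id
            raise KeyError(f"gene id not in catalog: {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "length_bp": self.length_bp})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneCatalog":
        return cls(frame["gene_id"].to_numpy(dtype=object), frame["length_bp"].to_numpy())


def simulate_gene_catalog(
    n_genes: int,
    log10_length_mean: float = 4.2,
    log10_length_sd: float = 0.6,
    seed: int = 0,
) -> GeneCatalog:
    """Draw a catalog with log-normal gene lengths.

    Lengths are ``round(10 ** Normal(mean, sd))`` clamped to >= 200 bp, which
    reproduces the long right tail of mammalian gene-span distributions (a
    median near ~16 kb with defaults and a few multi-hundred-kb genes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if log10_length_sd <= 0:
        raise ValueError("log10_length_sd must be > 0")
    rng = _rng(seed, 1)
    log10_len = rng.normal(log10_length_mean, log10_length_sd, size=n_genes)
    lengths = np.maximum(np.round(10.0 ** log10_len), 200).astype(np.int64)
    ids = np.array([f"gene{i + 1:06d}" for i in range(n_genes)], dtype=object)
    return GeneCatalog(ids, lengths)


# ---------------------------------------------------------------------------
# Expression under the lesion model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionModelParams:
    """Per-group parameters of the lesion expression model.

    Parameters
    ----------
    lambda_per_kb
        Expected transcription-blocking lesions per kb of gene.  A gene of
        length L kb keeps a fraction ``exp(-lambda * L)`` of its mean
        expression (zero-lesion probability of a Poisson count).
    baseline_log2_mean
        Mean log2 intensity of an undamaged, non-programmed gene.
    noise_sd_log2
        SD of multiplicative log-normal per-sample noise, on the log2 scale.
    prog_de_fraction
        Fraction of genes given a programmed (length-independent) expression
        change in this group, drawn independently of length so any length
        bias in DEG calls is attributable to ``lambda_per_kb`` alone.
    prog_de_log2fc
        Magnitude of the programmed log2 fold change; sign is ±1 with equal
        probability per programmed gene.
    """

    lambda_per_kb: float
    baseline_log2_mean: float = 8.0
    noise_sd_log2: float = 0.25
    prog_de_fraction: float = 0.0
    prog_de_log2fc: float = 1.0
    n_samples_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_per_kb < 0:
            raise ValueError("lambda_per_kb must be >= 0")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be > 0")
        if not 0.0 <= self.prog_de_fraction <= 1.0:
            raise ValueError("prog_de_fraction must be in [0, 1]")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")


#: The five experimental groups of the default truth scenario.  Dietary
#: restriction halves the lesion rate (it alleviates transcription stress);
#: rapamycin leaves it unchanged.
DEFAULT_GROUPS = ("WT-Control", "WT-DR", "Ercc1-Control", "Ercc1-Rapa", "Ercc1-DR")


def default_group_params(
    wt_lambda: float = 0.0,
    mutant_lambda: float = 0.004,
    dr_lambda_factor: float = 0.5,
    prog_de_fraction: float = 0.05,
    n_samples_per_group: int = 5,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
) -> list[tuple[str, LesionModelParams]]:
    """Default five-group truth scenario.

    WT groups carry no lesion load; the repair-deficient groups carry
    ``mutant_lambda`` per kb; DR multiplies a group's rate by
    ``dr_lambda_factor``; rapamycin does not change it.
    """

    def p(lam: float) -> LesionModelParams:
        return LesionModelParams(
            lambda_per_kb=lam,
            prog_de_fraction=prog_de_fraction,
            n_samples_per_group=n_samples_per_group,
            noise_sd_log2=noise_sd_log2,
            seed=seed,
        )

    return [
        ("WT-Control", p(wt_lambda)),
        ("WT-DR", p(wt_lambda * dr_lambda_factor)),
        ("Ercc1-Control", p(mutant_lambda)),
        ("Ercc1-Rapa", p(mutant_lambda)),
        ("Ercc1-DR", p(mutant_lambda * dr_lambda_factor)),
    ]


def simulate_expression(
    catalog: GeneCatalog,
    groups: Sequence[tuple[str, LesionModelParams]],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a linear-scale expression matrix under the lesion model.

    For a gene of length L kb in a group with rate lambda, the mean linear
    expression is ``2**baseline * exp(-lambda*L) * 2**(s*fc)`` where the last
    factor applies only to that group's programmed-DE subset (sign s = ±1);
    each sample then receives independent multiplicative log-normal noise of
    SD ``noise_sd_log2`` on the log2 scale.

    Returns
    -------
    (expression, design, truth)
        ``expression`` — genes × samples DataFrame of linear intensities;
        ``design`` — sample_id/group/sex table; ``truth`` — per-group lesion
        rates and programmed-gene maps (gene_id -> signed log2 fc).
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    labels = [label for label, _ in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    n_genes = len(catalog)
    length_kb = catalog.length_kb

    columns: list[str] = []
    design_rows: list[tuple[str, str, str]] = []
    blocks: list[np.ndarray] = []
    truth: dict = {"lambda_per_kb": {}, "programmed": {}}

    for label, params in groups:
        rng = _rng(params.seed, 2, _label_key(label))
        # programmed subset, independent of gene length by construction
        n_prog = int(round(params.prog_de_fraction * n_genes))
        prog_idx = rng.choice(n_genes, size=n_prog, replace=False) if n_prog else np.array([], int)
        signs = rng.choice([-1.0, 1.0], size=n_prog)
        prog_fc = np.zeros(n_genes)
        prog_fc[prog_idx] = signs * params.prog_de_log2fc

        mean_log2 = (
            params.baseline_log2_mean
            - params.lambda_per_kb * length_kb / _LN2
            + prog_fc
        )
        n = params.n_samples_per_group
        noise = rng.normal(0.0, params.noise_sd_log2, size=(n_genes, n))
        blocks.append(2.0 ** (mean_log2[:, None] + noise))

        for i in range(n):
            sample_id = f"{label}_{i + 1:02d}"
            columns.append(sample_id)
            design_rows.append((sample_id, label, "F" if i % 2 == 0 else "M"))

        truth["lambda_per_kb"][label] = params.lambda_per_kb
        truth["programmed"][label] = {
            catalog.gene_ids[j]: float(prog_fc[j]) for j in prog_idx
        }

    expression = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(catalog.gene_ids, name="gene_id"), columns=columns
    )
    design = pd.DataFrame(design_rows, columns=["sample_id", "group", "sex"])
    return expression, design, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard h(t) = a * exp(b*t), t in weeks; b=0 is exponential."""

    a: float
    b: float = 0.0
    n: int = 25

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("Gompertz scale a must be > 0")
        if self.b < 0:
            raise ValueError("Gompertz shape b must be >= 0")
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class SurvivalParams:
    groups: Mapping[str, GompertzParams]
    censor_time: float | None = None
    seed: int = 0


def simulate_survival(params: SurvivalParams) -> pd.DataFrame:
    """Draw event times by inverse-CDF from the Gompertz survivor function.

    ``S(t) = exp(-(a/b) (e^{bt} - 1))`` inverts to
    ``t = (1/b) ln(1 - (b/a) ln U)``; at b=0 the exponential ``-ln(U)/a``.
    Times beyond ``censor_time`` are recorded censored (event = 0) at the
    censor time.  Returns a table with columns
    ``animal_id, group, sex, time_weeks, event``.
    """
    rows = []
    for label, gp in params.groups.items():
        rng = _rng(params.seed, 3, _label_key(label))
        u = rng.uniform(size=gp.n)
        if gp.b == 0.0:
            t = -np.log(u) / gp.a
        else:
            t = np.log1p(-(gp.b / gp.a) * np.log(u)) / gp.b
        event = np.ones(gp.n, dtype=int)
        if params.censor_time is not None:
            censored = t > params.censor_time
            t = np.where(censored, params.censor_time, t)
            event = np.where(censored, 0, 1)
        for i in range(gp.n):
            rows.append(
                (
                    f"{label}-{i + 1:03d}",
                    label,
                    "F" if i % 2 == 0 else "M",
                    float(t[i]),
                    int(event[i]),
                )
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "sex", "time_weeks", "event"])


# ---------------------------------------------------------------------------
# Body weight
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSpec:
    """Deterministic weight trajectory of one group.

    ``w(t) = A - (A - w0) exp(-r (t - start))`` rises sigmoidally toward the
    asymptote A; once an animal passes ``decline_onset_frac`` of its lifespan
    the weight is additionally multiplied by
    ``exp(-decline_rate * (t - onset))`` (terminal wasting).
    """

    asymptote_g: float
    growth_rate_per_week: float = 0.35
    decline_rate_per_week: float = 0.0
    start_weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.asymptote_g <= 0:
            raise ValueError("asymptote must be > 0")
        if self.decline_rate_per_week < 0:
            raise ValueError("decline rate must be >= 0")

    def value(self, weeks: np.ndarray, start_week: float, death_week: float,
              decline_onset_frac: float) -> np.ndarray:
        w0 = self.start_weight_g if self.start_weight_g is not None else 0.4 * self.asymptote_g
        w = self.asymptote_g - (self.asymptote_g - w0) * np.exp(
            -self.growth_rate_per_week * (weeks - start_week)
        )
        onset = decline_onset_frac * death_week
        w = w * np.exp(-self.decline_rate_per_week * np.maximum(0.0, weeks - onset))
        return w


@dataclass(frozen=True)
class WeightParams:
    groups: Mapping[str, GrowthSpec]
    start_week: int = 8
    noise_sd_g: float = 0.5
    decline_onset_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_g < 0:
            raise ValueError("observation noise sd must be >= 0")


def simulate_weights(params: WeightParams, survival: pd.DataFrame) -> pd.DataFrame:
    """Weekly weights for every animal in ``survival``, until its death week.

    Weights are the group's deterministic growth curve plus independent
    Gaussian observation noise, recorded at integer weeks from
    ``params.start_week`` through ``floor(time_weeks)`` (animals dying before
    the start week contribute no rows).  Long format:
    ``animal_id, group, week, weight_g``.
    """
    missing = set(survival["group"]) - set(params.groups)
    if missing:
        raise ValueError(f"no trajectory spec for groups: {sorted(missing)}")
    rows = []
    for _, rec in survival.iterrows():
        spec = params.groups[rec["group"]]
        death_week = float(rec["time_weeks"])
        last = int(np.floor(death_week))
        if last < params.start_week:
            continue
        weeks = np.arange(params.start_week, last + 1)
        rng = _rng(params.seed, 4, zlib.crc32(str(rec["animal_id"]).encode()))
        w = spec.value(weeks.astype(float), params.start_week, death_week,
                       params.decline_onset_frac)
        if params.noise_sd_g > 0:
            w = w + rng.normal(0.0, params.noise_sd_g, size=w.size)
        w = np.maximum(w, 0.1)  # weights are physical, keep them positive
        for wk, wt in zip(weeks, w):
            rows.append((rec["animal_id"], rec["group"], int(wk), float(wt)))
    return pd.DataFrame(rows, columns=["animal_id", "group", "week", "weight_g"])


# ---------------------------------------------------------------------------
# Tissue point clouds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueVolume:
    """A sectioned tissue slab with cell-nucleus centroids.

    The slab spans ``[0, x_um) × [0, y_um)`` laterally and is cut into
    ``n_sections`` serial sections of ``cut_thickness_um`` each, so the total
    depth is ``n_sections * cut_thickness_um``.
    """

    x_um: float
    y_um: float
    n_sections: int
    cut_thickness_um: float
    points: np.ndarray  # (n, 3) coordinates in μm

    def __post_init__(self) -> None:
        if min(self.x_um, self.y_um, self.cut_thickness_um) <= 0 or self.n_sections < 1:
            raise ValueError("slab dimensions must be positive")
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        z = self.n_sections * self.cut_thickness_um
        if pts.size and (
            pts.min() < 0
            or pts[:, 0].max() >= self.x_um
            or pts[:, 1].max() >= self.y_um
            or pts[:, 2].max() >= z
        ):
            raise ValueError("all points must lie inside the slab")
        object.__setattr__(self, "points", pts)

    @property
    def z_um(self) -> float:
        return self.n_sections * self.cut_thickness_um

    @property
    def true_count(self) -> int:
        return int(self.points.shape[0])


def simulate_tissue(
    density_per_mm3: float,
    x_um: float,
    y_um: float,
    n_sections: int,
    cut_thickness_um: float,
    seed: int = 0,
) -> TissueVolume:
    """Homogeneous Poisson point process of nuclei in a slab."""
    if density_per_mm3 < 0:
        raise ValueError("density must be >= 0")
    if min(x_um, y_um, cut_thickness_um) <= 0 or n_sections < 1:
        raise ValueError("slab dimensions must be positive")
    rng = _rng(seed, 5)
    z_um = n_sections * cut_thickness_um
    volume_mm3 = x_um * y_um * z_um * 1e-9
    n = int(rng.poisson(density_per_mm3 * volume_mm3))
    pts = np.column_stack(
        [
            rng.uniform(0.0, x_um, size=n),
            rng.uniform(0.0, y_um, size=n),
            rng.uniform(0.0, z_um, size=n),
        ]
    )
    return TissueVolume(x_um, y_um, n_sections, cut_thickness_um, pts)
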