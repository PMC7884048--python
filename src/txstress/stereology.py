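"""Optical-fractionator stereology.

The optical fractionator estimates the total number of particles (here,
cell nuclei) in a structure from counts in a known fraction of the tissue:

    N = sum(Q-) * (t/h) * (1/asf) * (1/ssf)

where Q- are the particles counted in the disectors, t is the mounted
section thickness, h the disector (counting-frame) height, asf the area
sampling fraction (frame area / grid area), and ssf the section sampling
fraction (e.g. 1/8 when every 8th section is analysed).

Sampling uses systematic random sampling: every ``section_period``-th
section from a random start, with counting frames tiled at the grid spacing
from a uniformly random xy offset.  Nuclei are treated as points (centroid
abstraction) and unbiased counting rules are encoded as half-open
membership: a point is counted iff ``x in [x0, x0+frame_x)``,
``y in (y0, y0+frame_y]`` (excludes the "lower or right" frame sides) and
its depth lies within the disector, a band of height ``h`` within the
section excluding its upper surface plane.  By default the disector's depth
placement is itself randomized (uniform phase, wrapping within the section)
so that every point's inclusion probability is exactly ``h/t`` and the
estimator is unbiased conditional on the tissue; pass an explicit
``guard_um`` to pin the disector at a fixed depth ``[guard, guard+h)``
instead, as on a microscope with a fixed guard zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TissueVolume, _rng

__all__ = [
    "CountingDesign",
    "FrameCount",
    "FractionatorEstimate",
    "sample_frames",
    "fractionator_estimate",
    "frames_to_frame",
]


@dataclass(frozen=True)
class CountingDesign:
    """Stereological sampling parameters.

    ``section_period`` of 8 means every 8th section (ssf = 1/8).  The guard
    zone above the disector defaults to centring the disector in the
    section, ``(t - h)/2``.
    """

    frame_x_um: float
    frame_y_um: float
    grid_x_um: float
    grid_y_um: float
    mounted_thickness_um: float   # t
    disector_height_um: float     # h
    section_period: int = 1
    guard_um: float | None = None  # None -> random depth phase (exact SRS in z)

    def __post_init__(self) -> None:
        if not 0 < self.disector_height_um <= self.mounted_thickness_um:
            raise ValueError("need 0 < h <= t")
        if self.frame_x_um > self.grid_x_um or self.frame_y_um > self.grid_y_um:
            raise ValueError("counting frame must fit inside the grid cell")
        if min(self.frame_x_um, self.frame_y_um) <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.section_period < 1:
            raise ValueError("section_period must be >= 1")
        if self.guard_um is not None:
            g = self.guard_um
            if g < 0 or g + self.disector_height_um > self.mounted_thickness_um:
                raise ValueError("guard zone incompatible with t and h")

    @property
    def asf(self) -> float:
        return (self.frame_x_um * self.frame_y_um) / (self.grid_x_um * self.grid_y_um)

    @property
    def ssf(self) -> float:
        return 1.0 / self.section_period

    @property
    def thickness_ratio(self) -> float:
        return self.mounted_thickness_um / self.disector_height_um


@dataclass(frozen=True)
class FrameCount:
    section: int
    x0_um: float
    y0_um: float
    q_minus: int

    def __post_init__(self) -> None:
        if self.q_minus < 0:
            raise ValueError("q_minus must be >= 0")


def sample_frames(
    volume: TissueVolume,
    design: CountingDesign,
    seed: int = 0,
    offsets: tuple[int, float, float] | tuple[int, float, float, float] | None = None,
) -> list[FrameCount]:
    """Count nuclei in systematically sampled disector frames.

    Sections are taken every ``section_period``-th starting from a random
    section offset; frames tile each sampled section at the grid spacing
    from a random xy offset; the disector depth band gets a random phase
    unless the design fixes ``guard_um``.  Deterministic given ``seed``.
    ``offsets`` ``(section_start, x_offset_um, y_offset_um[, z_phase_um])``
    overrides the random offsets, e.g. to audit the counting rules.  Frames
    with zero counts are omitted from the returned list (they contribute
    nothing to the estimator).
    """
    if design.mounted_thickness_um != volume.cut_thickness_um:
        raise ValueError(
            "design mounted thickness must match the volume's cut thickness"
        )
    if offsets is None:
        rng = _rng(seed, 6)
        s0 = int(rng.integers(design.section_period))
        u = float(rng.uniform(0.0, design.grid_x_um))
        v = float(rng.uniform(0.0, design.grid_y_um))
        w = float(rng.uniform(0.0, design.mounted_thickness_um))
    else:
        s0, u, v = int(offsets[0]), float(offsets[1]), float(offsets[2])
        w = float(offsets[3]) if len(offsets) > 3 else 0.0

    pts = volume.points
    if pts.size == 0:
        return []
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    t_cut = volume.cut_thickness_um

    section = np.floor(z / t_cut).astype(int)
    z_in = z - section * t_cut
    in_section = (section % design.section_period) == (s0 % design.section_period)
    if design.guard_um is not None:
        g = design.guard_um
        in_disector = (z_in >= g) & (z_in < g + design.disector_height_um)
    else:
        # random depth phase wrapping within the section: inclusion
        # probability is exactly h/t for every point
        z_rel = np.mod(z_in - w, t_cut)
        in_disector = z_rel < design.disector_height_um

    kx = np.floor((x - u) / design.grid_x_um)
    dx = x - (u + kx * design.grid_x_um)
    in_x = dx < design.frame_x_um  # left edge in, right edge out

    ky = np.floor((y - v) / design.grid_y_um)
    dy = y - (v + ky * design.grid_y_um)
    in_y = (dy > 0.0) & (dy <= design.frame_y_um)  # lower side out, upper in

    counted = in_section & in_disector & in_x & in_y
    frames: dict[tuple[int, int, int], int] = {}
    for sec, i, j in zip(section[counted], kx[counted].astype(int), ky[counted].astype(int)):
        frames[(int(sec), i, j)] = frames.get((int(sec), i, j), 0) + 1
    return [
        FrameCount(
            section=sec,
            x0_um=u + i * design.grid_x_um,
            y0_um=v + j * design.grid_y_um,
            q_minus=q,
        )
        for (sec, i, j), q in sorted(frames.items())
    ]


@dataclass(frozen=True)
class FractionatorEstimate:
    n_hat: float
    sum_q: int
    thickness_ratio: float  # t/h
    inv_asf: float
    inv_ssf: float


def fractionator_estimate(
    counts: list[FrameCount], design: CountingDesign
) -> FractionatorEstimate:
    """Total population estimate N = sum(Q-) * (t/h) * (1/asf) * (1/ssf)."""
    if design.asf <= 0 or design.ssf <= 0 or design.disector_height_um <= 0:
        raise ValueError("sampling fractions and disector height must be positive")
    sum_q = int(sum(c.q_minus for c in counts))
    n_hat = sum_q * design.thickness_ratio * (1.0 / design.asf) * (1.0 / design.ssf)
    return FractionatorEstimate(
        n_hat=float(n_hat),
        sum_q=sum_q,
        thickness_ratio=design.thickness_ratio,
        inv_asf=1.0 / design.asf,
        inv_ssf=1.0 / design.ssf,
    )


def frames_to_frame(counts: list[FrameCount]) -> pd.DataFrame:
    """Frame counts as a CSV-ready table (section, x0, y0, q_minus)."""
    return pd.DataFrame(
        [(c.section, c.x0_um, c.y0_um, c.q_minus) for c in counts],
        columns=["section", "x0_um", "y0_um", "q_minus"],
    )
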