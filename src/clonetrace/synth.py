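"""Synthetic data generators mirroring the pipeline's input structure.

Every analysis stage has a paired generator that emits observations plus the
ground truth needed to score that stage: exponential clone trajectories over
the sampling grid (days 0/21/57/91) with multiplicative log-normal noise,
barcoded reads with a 250-nt barcode body, 15-nt clone tag and the 33-nt
vector anchor, inferred-CNV matrices with block amplifications/deletions,
and paired point patterns with a controllable patch co-occurrence. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_TIMES,
    FATE_MULTIFATE,
    FATE_PERSISTER,
    FATE_SENSITIVE,
    TumorContext,
)
from .extract import DEFAULT_ANCHOR, ReadRecord
from .spatial import BoundingBox, PointSet

__all__ = [
    "DynamicsSimConfig",
    "ReadSimConfig",
    "SimulatedDynamics",
    "SimulatedReads",
    "SimulatedCNV",
    "SimulatedPoints",
    "simulate_clone_dynamics",
    "simulate_reads",
    "simulate_cnv_matrix",
    "simulate_colocalized_points",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class DynamicsSimConfig:
    """Ground-truth model for longitudinal clone trajectories.

    Sensitive clones decay as A·e^(−kt) with k ~ U(0.05, 0.2)/day, persisters
    grow as A·e^(+kt) with k ~ U(0.02, 0.08)/day, and multi-fate clones stay
    at a low constant level. Initial clone masses within each fate follow a
    symmetric Dirichlet (``concentration`` controls evenness); sensitive
    clones hold most of the pre-treatment tumor. Observation noise is
    multiplicative log-normal on each clone mass.
    """

    times: Sequence[float] = DEFAULT_TIMES
    n_sensitive: int = 100
    n_persister: int = 100
    n_multifate: int = 100
    decay_rate_range: tuple[float, float] = (0.05, 0.2)
    growth_rate_range: tuple[float, float] = (0.02, 0.08)
    noise_sd: float = 0.05
    sensitive_share: float = 0.95
    persister_share: float = 0.05
    multifate_amplitude_range: tuple[float, float] = (1e-6, 5e-6)
    concentration: float = 5.0
    peak_volume_mm3: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitive + self.n_persister + self.n_multifate == 0:
            raise ValueError("empty fate mix")
        for lo, hi in (self.decay_rate_range, self.growth_rate_range):
            if not (0 < lo <= hi):
                raise ValueError("rate ranges must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")


@dataclass
class SimulatedDynamics:
    proportions: pd.DataFrame  # clones x times, columns are day values
    contexts: list[TumorContext]
    truth: pd.DataFrame  # index clone_tag: fate, amplitude, rate


def simulate_clone_dynamics(config: DynamicsSimConfig) -> SimulatedDynamics:
    """Simulate clone proportions over the sampling grid plus tumor contexts.

    True clone masses follow their fate's closed form; noisy masses are
    renormalized per time point into proportions. Tumor volume is taken
    proportional to total clone mass, scaled to ``peak_volume_mm3`` at day 0,
    so the proportion-times-volume normalization recovers each clone's
    exponential mass trajectory — the decline-and-regrowth volume curve under
    therapy then emerges from the fate mix itself. Activity factors are 1.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)

    tags, fates, amps, rates = [], [], [], []

    def _fate_block(n: int, share: float, fate: str, rate_range) -> None:
        if n == 0:
            return
        w = rng.dirichlet(np.full(n, config.concentration))
        for i in range(n):
            tags.append(f"{fate[:4].upper()}{i:05d}")
            fates.append(fate)
            amps.append(share * w[i])
            if rate_range is None:
                rates.append(0.0)
            else:
                rates.append(rng.uniform(*rate_range))

    _fate_block(config.n_sensitive, config.sensitive_share, FATE_SENSITIVE,
                config.decay_rate_range)
    _fate_block(config.n_persister, config.persister_share, FATE_PERSISTER,
                config.growth_rate_range)
    if config.n_multifate:
        lo, hi = config.multifate_amplitude_range
        for i in range(config.n_multifate):
            tags.append(f"MULT{i:05d}")
            fates.append(FATE_MULTIFATE)
            amps.append(rng.uniform(lo, hi))
            rates.append(0.0)

    amps_arr = np.array(amps)
    rates_arr = np.array(rates)
    sign = np.array(
        [{FATE_SENSITIVE: -1.0, FATE_PERSISTER: 1.0, FATE_MULTIFATE: 0.0}[f]
         for f in fates]
    )
    mass = amps_arr[:, None] * np.exp(sign[:, None] * rates_arr[:, None] * t[None, :])
    if config.noise_sd > 0:
        mass = mass * np.exp(rng.normal(0.0, config.noise_sd, size=mass.shape))

    totals = mass.sum(axis=0)
    props = mass / totals[None, :]
    volumes = config.peak_volume_mm3 * totals / totals[0]
    contexts = [TumorContext(time=float(ti), volume=float(v)) for ti, v in zip(t, volumes)]
    proportions = pd.DataFrame(props, index=tags, columns=[float(x) for x in t])
    truth = pd.DataFrame(
        {"fate": fates, "amplitude": amps_arr, "rate": rates_arr}, index=tags
    )
    truth.index.name = "clone_tag"
    return SimulatedDynamics(proportions=proportions, contexts=contexts, truth=truth)


@dataclass(frozen=True)
class ReadSimConfig:
    """Anatomy and error model for simulated barcode-transcript reads.

    Each read is: left flank + 250-nt barcode body + 15-nt clone tag + 33-nt
    vector anchor + right flank, with i.i.d. substitution errors and roughly
    half the reads emitted reverse-complemented. Cell tags (16 nt) and UMIs
    (12 nt) ride along as read metadata.
    """

    n_clones: int = 50
    clone_tags: Optional[Sequence[str]] = None
    cells_per_clone: int = 5
    reads_per_cell: int = 4
    error_rate: float = 0.0
    anchor: str = DEFAULT_ANCHOR
    barcode_body_len: int = 250
    flank_lens: tuple[int, int] = (8, 8)
    cell_tag_len: int = 16
    umi_len: int = 12
    revcomp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.2):
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.clone_tags is not None:
            if len(set(self.clone_tags)) != len(self.clone_tags):
                raise ValueError("clone tags must be distinct")


@dataclass
class SimulatedReads:
    reads: list[ReadRecord]
    cell_to_clone: dict[str, str]  # cell tag -> true clone tag
    clone_barcodes: dict[str, str]  # clone tag -> full barcode (body + tag)
    truth_table: pd.DataFrame  # expected error-free TagCountTable


def simulate_reads(config: ReadSimConfig) -> SimulatedReads:
    """Generate barcoded reads with known per-cell clone identity."""
    rng = np.random.default_rng(config.seed)
    if config.clone_tags is None:
        tags: list[str] = []
        seen: set[str] = set()
        while len(tags) < config.n_clones:
            s = _random_seq(rng, 15)
            if s not in seen:
                seen.add(s)
                tags.append(s)
    else:
        tags = [t.upper() for t in config.clone_tags]

    barcodes = {t: _random_seq(rng, config.barcode_body_len) + t for t in tags}

    cell_to_clone: dict[str, str] = {}
    used_cells: set[str] = set()
    reads: list[ReadRecord] = []
    rows = []
    comp = str.maketrans("ACGT", "TGCA")
    n = 0
    for tag in tags:
        for _ in range(config.cells_per_clone):
            while True:
                cell = _random_seq(rng, config.cell_tag_len)
                if cell not in used_cells:
                    used_cells.add(cell)
                    break
            cell_to_clone[cell] = tag
            umis = set()
            for _ in range(config.reads_per_cell):
                umi = _random_seq(rng, config.umi_len)
                umis.add(umi)
                seq = (
                    _random_seq(rng, config.flank_lens[0])
                    + barcodes[tag]
                    + config.anchor
                    + _random_seq(rng, config.flank_lens[1])
                )
                if config.error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                    hits = np.nonzero(rng.random(len(seq)) < config.error_rate)[0]
                    for i in hits:
                        alts = [b for b in "ACGT" if b != arr[i]]
                        arr[i] = alts[rng.integers(3)]
                    seq = "".join(arr)
                if rng.random() < config.revcomp_fraction:
                    seq = seq.translate(comp)[::-1]
                n += 1
                reads.append(
                    ReadRecord(read_id=f"r{n:07d}", sequence=seq, cell_tag=cell, umi=umi)
                )
            rows.append((cell, tag, config.reads_per_cell, len(umis)))
    truth = pd.DataFrame(
        sorted(rows), columns=["cell_tag", "clone_tag", "read_count", "umi_count"]
    )
    return SimulatedReads(
        reads=reads,
        cell_to_clone=cell_to_clone,
        clone_barcodes=barcodes,
        truth_table=truth,
    )


@dataclass
class SimulatedCNV:
    cnv: pd.DataFrame  # cells x genes, centered at 1
    expression: pd.DataFrame  # cells x genes, nonnegative
    cell_groups: pd.Series  # cell -> group
    true_fraction: pd.Series  # cell -> fraction of genes outside the band


def simulate_cnv_matrix(
    n_cells: int,
    n_genes: int,
    deviating_fraction: Mapping[str, float],
    coupled_groups: Sequence[str] = (),
    seed: int = 0,
) -> SimulatedCNV:
    """Inferred-CNV matrices with block amplifications/deletions per group.

    Cells are split evenly among the groups (sorted order). Baseline values
    are Normal(1, 0.02) clipped inside the neutral band; each group's stated
    fraction of genes is moved into an amplified block (~1.3) at the start of
    the gene axis and a deleted block (~0.7) at the end, so the per-cell CNV
    score recovers the fraction by construction. Groups listed in
    ``coupled_groups`` get expression multiplicatively coupled to their CNV
    (expression ~ base · cnv^3 · noise); others get independent expression.
    """
    for g, f in deviating_fraction.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"group {g!r}: fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    group_names = sorted(deviating_fraction)
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    genes = [f"gene{j:05d}" for j in range(n_genes)]
    assignment = [group_names[i % len(group_names)] for i in range(n_cells)]

    cnv = rng.normal(1.0, 0.02, size=(n_cells, n_genes))
    np.clip(cnv, 0.905, 1.095, out=cnv)
    true_frac = np.zeros(n_cells)
    for i, grp in enumerate(assignment):
        m = int(round(deviating_fraction[grp] * n_genes))
        n_amp = (m + 1) // 2
        n_del = m - n_amp
        if n_amp:
            amp = np.clip(rng.normal(1.3, 0.03, size=n_amp), 1.15, None)
            cnv[i, :n_amp] = amp
        if n_del:
            dele = np.clip(rng.normal(0.7, 0.03, size=n_del), None, 0.85)
            cnv[i, n_genes - n_del :] = dele
        true_frac[i] = m / n_genes

    base = rng.lognormal(mean=2.0, sigma=0.5, size=n_genes)
    noise = rng.lognormal(mean=0.0, sigma=0.1, size=(n_cells, n_genes))
    coupled = np.array([g in set(coupled_groups) for g in assignment])
    expr = base[None, :] * noise
    expr[coupled] = expr[coupled] * cnv[coupled] ** 3

    return SimulatedCNV(
        cnv=pd.DataFrame(cnv, index=cells, columns=genes),
        expression=pd.DataFrame(expr, index=cells, columns=genes),
        cell_groups=pd.Series(assignment, index=cells, name="group"),
        true_fraction=pd.Series(true_frac, index=cells, name="true_fraction"),
    )


@dataclass
class SimulatedPoints:
    pointsA: PointSet
    pointsB: PointSet
    occupied_a: np.ndarray  # boolean (g, g)
    occupied_b: np.ndarray
    gen_grid: int


def simulate_colocalized_points(
    n_patches_hint: int = 64,
    co_occurrence: float = 0.9,
    points_per_patch: float = 3.0,
    box: BoundingBox | None = None,
    occupancy: float = 0.2,
    seed: int = 0,
) -> SimulatedPoints:
    """Paired point patterns with a controllable patch-level co-occurrence.

    A latent g x g grid (g ≈ sqrt(n_patches_hint)) drives occupancy: channel
    A occupies each patch independently with probability ``occupancy``
    (default 0.2 — a minority clone's spots are sparse in a section); for
    every A-occupied patch, channel B occupies the same patch with
    probability ``co_occurrence`` and an independently chosen uniform patch
    otherwise — so ``co_occurrence = 0`` is full independence. Each occupied
    patch receives 1 + Poisson(points_per_patch − 1) uniformly scattered
    points.
    """
    if not (0.0 <= co_occurrence <= 1.0):
        raise ValueError("co_occurrence must be in [0, 1]")
    box = box or BoundingBox(0.0, 0.0, 100.0, 100.0)
    g = max(2, int(round(np.sqrt(n_patches_hint))))
    rng = np.random.default_rng(seed)

    occ_a = rng.random((g, g)) < occupancy
    occ_b = np.zeros((g, g), dtype=bool)
    for iy, ix in zip(*np.nonzero(occ_a)):
        if rng.random() < co_occurrence:
            occ_b[iy, ix] = True
        else:
            occ_b[rng.integers(g), rng.integers(g)] = True

    def _scatter(occ: np.ndarray) -> np.ndarray:
        pw, ph = box.width / g, box.height / g
        pts = []
        for iy, ix in zip(*np.nonzero(occ)):
            k = 1 + rng.poisson(max(points_per_patch - 1.0, 0.0))
            xs = box.x0 + (ix + rng.random(k)) * pw
            ys = box.y0 + (iy + rng.random(k)) * ph
            pts.append(np.column_stack([xs, ys]))
        if not pts:
            return np.empty((0, 2))
        return np.vstack(pts)

    pa = PointSet(label="A", points=_scatter(occ_a), box=box)
    pb = PointSet(label="B", points=_scatter(occ_b), box=box)
    return SimulatedPoints(
        pointsA=pa, pointsB=pb, occupied_a=occ_a, occupied_b=occ_b, gen_grid=g
    )
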