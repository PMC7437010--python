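"""Pooled-competition simulator with planted ground truth.

Emulates a barcoded deletion-library scale-up experiment: a heavy-tailed
initial pool passes through a two-stage seed train (with serial-transfer
bottlenecks) and branches into shake-flask, batch, and fed-batch conditions.
Within each process phase of ``g`` generations a mutant's relative abundance
updates multiplicatively, ``x_i <- x_i * (1 + s_i)^g`` followed by
renormalization, where ``s_i`` is the mutant's per-generation selection
coefficient in that phase (0 = neutral, negative = selected against).
Stressful intervals — e.g. the ethanol accumulation seen in overfed
constant-rate fed-batch reactors — are modeled as phases in which a planted
subset of mutants carries strongly negative ``s``, not as a mechanistic
fermentation model: the downstream analysis only consumes the abundance
consequences.

Sequencing is a multinomial draw at a configurable depth, and reads can be
emitted as FASTQ with per-base substitution errors to exercise the
perfect-match counting rule end to end.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .barcode_quant import BarcodeCatalog, CountTable, SampleMeta

# Invented amplicon layout: barcode follows this upstream flank in each read.
DEFAULT_FLANK = "GTCGACCTGCAGCGTACG"


@dataclass(frozen=True)
class Phase:
    phase_id: str
    condition: str
    start_h: float
    end_h: float
    generations: float
    bottleneck_cells: int | None = None

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError(f"phase {self.phase_id}: end_h must exceed start_h")
        if self.generations <= 0:
            raise ValueError(f"phase {self.phase_id}: generations must be > 0")


@dataclass
class ProcessSchedule:
    """Ordered, non-overlapping phases per condition plus the lineage.

    ``parent`` maps each condition to the condition whose final state seeds
    it (``None`` for the root of the seed train). Sampling times are the
    phase boundaries.
    """

    phases: list[Phase]
    parent: dict[str, str | None]
    vessels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.conditions():
            ph = self.phases_for(cond)
            for a, b in zip(ph, ph[1:]):
                if b.start_h < a.end_h:
                    raise ValueError(
                        f"overlapping phases in {cond!r}: {a.phase_id}, {b.phase_id}"
                    )
        ids = [p.phase_id for p in self.phases]
        if len(ids) != len(set(ids)):
            raise ValueError("phase ids must be unique")
        unknown_parents = {
            p for p in self.parent.values() if p is not None
        } - set(self.parent)
        if unknown_parents:
            raise ValueError(f"unknown parent condition(s) {unknown_parents}")

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for p in self.phases:
            if p.condition not in seen:
                seen.append(p.condition)
        return seen

    def phases_for(self, condition: str) -> list[Phase]:
        return sorted(
            (p for p in self.phases if p.condition == condition),
            key=lambda p: p.start_h,
        )

    def times_for(self, condition: str) -> list[float]:
        ph = self.phases_for(condition)
        return [ph[0].start_h] + [p.end_h for p in ph]

    def topological_conditions(self) -> list[str]:
        ordered: list[str] = []
        remaining = set(self.conditions())
        while remaining:
            progressed = False
            for cond in list(remaining):
                par = self.parent.get(cond)
                if par is None or par in ordered:
                    ordered.append(cond)
                    remaining.discard(cond)
                    progressed = True
            if not progressed:
                raise ValueError(f"lineage cycle among {sorted(remaining)}")
        return ordered


@dataclass
class FitnessLandscape:
    """Per-gene, per-phase selection coefficients (genes x phases matrix)."""

    genes: list[str]
    phase_ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.genes), len(self.phase_ids)):
            raise ValueError("s must be genes x phases")
        if not np.isfinite(self.s).all():
            raise ValueError("selection coefficients must be finite")
        if len(set(self.phase_ids)) != len(self.phase_ids):
            raise ValueError("phase ids must be unique")

    def s_for(self, phase_id: str) -> np.ndarray:
        if phase_id not in self.phase_ids:
            return np.zeros(len(self.genes))
        return self.s[:, self.phase_ids.index(phase_id)]

    def planted_deleterious(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.s < 0)
        return {(self.genes[r], self.phase_ids[c]) for r, c in zip(rows, cols)}


@dataclass
class SimTruth:
    """Planted ground truth: exact relative abundances per (condition, time)."""

    genes: list[str]
    abundances: dict[tuple[str, float], np.ndarray]
    planted_deleterious: set[tuple[str, str]]
    seed: int | None
    vessels: dict[str, str] = field(default_factory=dict)

    def abundance(self, condition: str, time_h: float) -> np.ndarray:
        key = (condition, float(time_h))
        if key not in self.abundances:
            raise KeyError(f"no truth for {condition!r} at {time_h} h")
        return self.abundances[key]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in self.abundances:
            if cond not in seen:
                seen.append(cond)
        return seen

    def times_for(self, condition: str) -> list[float]:
        return sorted(t for c, t in self.abundances if c == condition)

    def planted_genes(self, condition: str, t_start_h: float, t_end_h: float) -> set[str]:
        """Genes planted deleterious in the phase spanning the given window."""
        token = f"{condition}:{t_start_h:g}-{t_end_h:g}"
        return {g for g, pid in self.planted_deleterious if pid == token}


def lognormal_initial_abundance(
    n_genes: int, sigma: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Heavy-tailed initial pool: normalized log-normal draws.

    A log-normal with sigma ~= 1 mimics the uneven colony-pooled libraries
    seen in practice, where a substantial minority of strains sits below any
    fixed detection threshold at realistic sequencing depth.
    """
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    return x / x.sum()


def simulate_trajectory(
    landscape: FitnessLandscape,
    schedule: ProcessSchedule,
    initial_abundance: np.ndarray | None = None,
    seed: int | None = None,
) -> SimTruth:
    """Deterministic-selection trajectory with optional transfer bottlenecks.

    Phases execute in lineage order; a condition inherits its parent's final
    state. Truth is recorded at every phase boundary *before* any bottleneck,
    since samples are drawn from the outgoing culture; the multinomial
    bottleneck (``bottleneck_cells`` cells) then resamples the pool that is
    carried forward, modeling serial-transfer drift.
    """
    rng = np.random.default_rng(seed)
    n = len(landscape.genes)
    if initial_abundance is None:
        x0 = lognormal_initial_abundance(n, seed=rng.integers(2**31))
    else:
        x0 = np.asarray(initial_abundance, dtype=float)
        if x0.shape != (n,):
            raise ValueError("initial_abundance length must match genes")
        x0 = x0 / x0.sum()

    abundances: dict[tuple[str, float], np.ndarray] = {}
    final_state: dict[str, np.ndarray] = {}
    for cond in schedule.topological_conditions():
        parent = schedule.parent.get(cond)
        x = (x0 if parent is None else final_state[parent]).copy()
        phases = schedule.phases_for(cond)
        abundances[(cond, float(phases[0].start_h))] = x.copy()
        for phase in phases:
            s = landscape.s_for(phase.phase_id)
            if np.any(1.0 + s <= 0.0):
                raise ValueError(
                    f"phase {phase.phase_id}: (1 + s) must be positive; "
                    "encode lethality as s = -1 + eps"
                )
            x = x * (1.0 + s) ** phase.generations
            x = x / x.sum()
            abundances[(cond, float(phase.end_h))] = x.copy()
            if phase.bottleneck_cells:
                draw = rng.multinomial(int(phase.bottleneck_cells), x)
                x = draw / draw.sum()
        final_state[cond] = x
    return SimTruth(
        genes=list(landscape.genes),
        abundances=abundances,
        planted_deleterious=landscape.planted_deleterious(),
        seed=seed,
        vessels=dict(schedule.vessels),
    )


def sample_reads(
    truth: SimTruth,
    condition: str,
    time_h: float,
    depth: int,
    seed: int | None = None,
    sample_id: str | None = None,
) -> CountTable:
    """Multinomial sequencing of one (condition, timepoint): depth reads."""
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    x = truth.abundance(condition, time_h)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), x)
    meta = SampleMeta(
        sample_id=sample_id or f"{condition}_t{time_h:g}",
        condition=condition,
        vessel=truth.vessels.get(condition, "bioreactor"),
        time_h=float(time_h),
    )
    return CountTable.from_samples([(meta, dict(zip(truth.genes, counts)))])


def sample_all(truth: SimTruth, depth: int, seed: int | None = None) -> CountTable:
    """Sequence every (condition, timepoint) of the truth at equal depth."""
    ss = np.random.SeedSequence(seed)
    keys = sorted(truth.abundances, key=lambda k: (k[0], k[1]))
    child_seeds = ss.generate_state(len(keys)) % (2**31)
    tables = [
        sample_reads(truth, cond, t, depth, seed=int(s))
        for (cond, t), s in zip(keys, child_seeds)
    ]
    table = tables[0]
    for other in tables[1:]:
        table = table.concat(other)
    return table


def random_catalog(
    n_genes: int, barcode_length: int = 20, seed: int | None = None
) -> BarcodeCatalog:
    """Distinct random barcodes, one per synthetic mutant."""
    rng = np.random.default_rng(seed)
    barcodes: set[str] = set()
    while len(barcodes) < n_genes:
        draw = rng.integers(0, 4, size=(n_genes - len(barcodes), barcode_length))
        for row in draw:
            barcodes.add("".join("ACGT"[b] for b in row))
    width = len(str(n_genes))
    entries = [
        (bc, f"mut{i + 1:0{width}d}") for i, bc in enumerate(sorted(barcodes))
    ]
    return BarcodeCatalog(entries=entries)


def emit_fastq(
    counts: CountTable,
    catalog: BarcodeCatalog,
    path: str | Path,
    upstream_flank: str = DEFAULT_FLANK,
    error_rate: float = 0.0,
    read_length: int = 60,
    seed: int | None = None,
    apply_flank_errors: bool = False,
) -> Path:
    """Write one read per count: random prefix + flank + barcode + suffix.

    Substitution errors hit barcode bases independently at ``error_rate``
    (opt-in also the flank, to exercise flank-miss dropout); the random
    prefix is redrawn if it would create a spurious earlier flank
    occurrence, so an error-free emission round-trips exactly through the
    perfect-match counter. Quality is a constant string.
    """
    if counts.n_samples != 1:
        raise ValueError("emit_fastq takes a single-sample count table")
    L = catalog.barcode_length
    flank_len = len(upstream_flank)
    if flank_len + L > read_length:
        raise ValueError(
            f"flank ({flank_len}) + barcode ({L}) exceed read_length {read_length}"
        )
    mapping = {gene: catalog.barcode_for(gene) for gene in counts.genes
               if counts.counts.iloc[0][gene] > 0}
    rng = np.random.default_rng(seed)
    budget = read_length - flank_len - L
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    quality = "I" * read_length
    idx = 0
    with opener(path, "wt") as fh:  # type: ignore[operator]
        row = counts.counts.iloc[0]
        for gene in counts.genes:
            c = int(row[gene])
            if c == 0:
                continue
            barcode = mapping[gene]
            for _ in range(c):
                for _attempt in range(100):
                    p = int(rng.integers(0, budget + 1))
                    prefix = _random_dna(rng, p)
                    suffix = _random_dna(rng, budget - p)
                    read = prefix + upstream_flank + barcode + suffix
                    if read.find(upstream_flank) == p:
                        break
                else:  # pragma: no cover - astronomically unlikely
                    raise RuntimeError("could not place flank unambiguously")
                if error_rate > 0.0:
                    lo = p if apply_flank_errors else p + flank_len
                    hi = p + flank_len + L
                    read = _mutate(read, lo, hi, error_rate, rng)
                fh.write(f"@r{idx} gene={gene}\n{read}\n+\n{quality}\n")
                idx += 1
    return path


def _random_dna(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def _mutate(
    read: str, lo: int, hi: int, error_rate: float, rng: np.random.Generator
) -> str:
    chars = list(read)
    hits = np.flatnonzero(rng.random(hi - lo) < error_rate)
    for offset in hits:
        i = lo + int(offset)
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def synthetic_annotation(
    genes: list[str],
    planted_genes: set[str] | frozenset[str],
    seed: int | None = None,
    planted_term: str = "T_stress",
    coverage: float = 0.8,
    n_decoy_terms: int = 30,
    decoy_size: tuple[int, int] = (10, 60),
):
    """Synthetic gene->term annotation with one term planted on a gene set.

    The planted term covers ``coverage`` of ``planted_genes`` plus a few
    random background genes (so it is enriched in, not identical to, a
    recovered list); decoy terms are random draws from the background.
    Returns an :class:`~barseq_popdyn.selection_enrichment.AnnotationMap`
    whose background is ``genes``.
    """
    from .selection_enrichment import AnnotationMap

    rng = np.random.default_rng(seed)
    planted = sorted(set(planted_genes))
    others = sorted(set(genes) - set(planted))
    n_core = max(1, int(round(coverage * len(planted))))
    core = list(rng.choice(planted, size=n_core, replace=False))
    n_noise = max(1, n_core // 10)
    noise = list(rng.choice(others, size=min(n_noise, len(others)),
                            replace=False))
    gene_terms: dict[str, set[str]] = {}
    descriptions = {planted_term: "planted stress-response term"}
    for g in core + noise:
        gene_terms.setdefault(g, set()).add(planted_term)
    for i in range(n_decoy_terms):
        term = f"T_decoy{i + 1:02d}"
        descriptions[term] = f"decoy term {i + 1}"
        size = int(rng.integers(decoy_size[0], decoy_size[1] + 1))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            gene_terms.setdefault(str(g), set()).add(term)
    return AnnotationMap(
        term_descriptions=descriptions,
        gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
        background=frozenset(genes),
    )


# ---------------------------------------------------------------------------
# Study-layout preset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressSpec:
    """A planted stress window: ``n`` or ``fraction`` genes get coefficient s."""

    condition: str
    t_start_h: float
    t_end_h: float
    s: float
    n: int | None = None
    fraction: float | None = None

    def resolve_n(self, n_genes: int) -> int:
        if (self.n is None) == (self.fraction is None):
            raise ValueError("specify exactly one of n or fraction")
        return self.n if self.n is not None else int(round(self.fraction * n_genes))


MAIN_TIMES_FEDBATCH = (0.0, 5.0, 24.0, 33.0, 48.0, 72.0, 119.0)
MAIN_TIMES_BATCH = (0.0, 5.0, 24.0, 33.0, 48.0, 72.0)
BATCH_END_H = 33.0  # glucose exhausted; feed (or stationary phase) begins

#: Default planted stresses: severe fitness deficits during the late
#: ethanol-stress window of the constant-feed reactors (strongest in CF6,
#: which also starts losing diversity earlier), a milder one in DF4, and a
#: near-neutral DF6 — mirroring the qualitative ordering of diversity
#: collapse across feeding regimes.
DEFAULT_STRESS = (
    StressSpec("CF4", 48.0, 72.0, s=-0.90, fraction=0.12),
    StressSpec("CF6", 33.0, 48.0, s=-0.85, fraction=0.20),
    StressSpec("CF6", 48.0, 72.0, s=-0.92, fraction=0.35),
    StressSpec("DF4", 48.0, 72.0, s=-0.85, fraction=0.10),
)

SEED_GENERATIONS = 5.0
BATCH_GENERATIONS = 7.0
FEDBATCH_GENERATIONS_PER_INTERVAL = 6.0
# Post-glucose shake-flask/batch intervals: little residual growth.
STATIONARY_GENERATIONS = (2.0, 1.0)


def preset_scaleup_design(
    seed: int | None = None,
    n_genes: int = 3000,
    stress_specs: tuple[StressSpec, ...] | list[StressSpec] | None = None,
    bottleneck_cells: int | None = 1_000_000,
) -> tuple[FitnessLandscape, ProcessSchedule]:
    """The study layout: shared seed train, then seven main conditions.

    Two 24 h seed stages (Seed1 -> Seed2, shake flasks, serial-transfer
    bottlenecks) feed shake flasks SF1/SF2 and a batch bioreactor BR (sampled
    0/5/24/33/48/72 h) and four fed-batch bioreactors CF4/CF6/DF4/DF6
    (sampled through 119 h). Batch-phase growth (0-33 h) carries 7
    generations split across sampling intervals in proportion to duration;
    each fed-batch interval carries 6 further generations. Stress windows
    plant negative selection coefficients per ``stress_specs``
    (:data:`DEFAULT_STRESS` when None; pass ``[]`` for a fully neutral
    landscape). Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if stress_specs is None:
        stress_specs = DEFAULT_STRESS

    phases: list[Phase] = []
    parent: dict[str, str | None] = {"Seed1": None, "Seed2": "Seed1"}
    vessels: dict[str, str] = {"Seed1": "shake_flask", "Seed2": "shake_flask"}

    phases.append(Phase("Seed1:0-24", "Seed1", 0.0, 24.0,
                        SEED_GENERATIONS, bottleneck_cells))
    phases.append(Phase("Seed2:0-24", "Seed2", 0.0, 24.0,
                        SEED_GENERATIONS, bottleneck_cells))

    mains = {
        "SF1": (MAIN_TIMES_BATCH, "shake_flask"),
        "SF2": (MAIN_TIMES_BATCH, "shake_flask"),
        "BR": (MAIN_TIMES_BATCH, "bioreactor"),
        "CF4": (MAIN_TIMES_FEDBATCH, "bioreactor"),
        "CF6": (MAIN_TIMES_FEDBATCH, "bioreactor"),
        "DF4": (MAIN_TIMES_FEDBATCH, "bioreactor"),
        "DF6": (MAIN_TIMES_FEDBATCH, "bioreactor"),
    }
    for cond, (times, vessel) in mains.items():
        parent[cond] = "Seed2"
        vessels[cond] = vessel
        fedbatch = times is MAIN_TIMES_FEDBATCH
        post_batch_idx = 0
        for t0, t1 in zip(times, times[1:]):
            if t1 <= BATCH_END_H:
                gens = BATCH_GENERATIONS * (t1 - t0) / BATCH_END_H
            elif fedbatch:
                gens = FEDBATCH_GENERATIONS_PER_INTERVAL
            else:
                gens = STATIONARY_GENERATIONS[
                    min(post_batch_idx, len(STATIONARY_GENERATIONS) - 1)
                ]
                post_batch_idx += 1
            phases.append(Phase(f"{cond}:{t0:g}-{t1:g}", cond, t0, t1, gens))

    schedule = ProcessSchedule(phases=phases, parent=parent, vessels=vessels)

    width = len(str(n_genes))
    genes = [f"mut{i + 1:0{width}d}" for i in range(n_genes)]
    phase_ids = [p.phase_id for p in schedule.phases]
    s = np.zeros((n_genes, len(phase_ids)))
    for spec in stress_specs:
        pid = f"{spec.condition}:{spec.t_start_h:g}-{spec.t_end_h:g}"
        if pid not in phase_ids:
            raise ValueError(f"stress window {pid!r} is not a schedule phase")
        if not -1.0 < spec.s:
            raise ValueError("stress s must exceed -1 (use -1 + eps for lethal)")
        n_hit = spec.resolve_n(n_genes)
        hit = rng.choice(n_genes, size=n_hit, replace=False)
        s[hit, phase_ids.index(pid)] = spec.s
    landscape = FitnessLandscape(genes=genes, phase_ids=phase_ids, s=s)
    return landscape, schedule
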