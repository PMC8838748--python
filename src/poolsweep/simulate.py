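"""Clonal Wright-Fisher simulation of pooled-sequencing experiments.

The simulator produces variant tables with known ground truth so every
downstream stage (artifact filtering, selection estimation, repeatability)
can be validated without external data. It emulates the statistical
structure of an evolve-and-resequence experiment on a clonal dsDNA virus:

* genotype-class Wright-Fisher dynamics without recombination — each class
  is a set of mutations with multiplicative fitness ``prod(1 + s_i)``;
  next-generation class counts are multinomial at the current population
  size;
* de-novo mutation at rate ``mu`` per site per replication (Poisson number
  of mutants per generation, uniform positions, parent class drawn by
  frequency);
* demography profiles: ``constant`` N, or ``bottleneck`` with periodic
  crashes to ``N_min`` (a stylization of serial predator-prey population
  collapse);
* pooled sequencing: per (site, sample) depth ~ Poisson(depth_mean) and alt
  reads ~ Binomial(depth, f(1-e) + (1-f)e) with symmetric error e;
* injected artifact variants of the two kinds the filters target:
  constant-frequency sites and batch-wide polymorphic sites.

Population size defaults to a scaled-down effective size of 1e5 rather than
the experimental census of ~1e10: at such sizes the frequency dynamics of
the modeled sweeps are effectively deterministic, and the class-based
multinomial at census scale would add nothing but cost. A fully
deterministic (infinite-N) mode is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    BASES,
    GenomeAnnotation,
    ORF,
    SampleMeta,
    Treatment,
    VariantSite,
    VariantTable,
)

_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOP_CODONS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ArtifactSpec:
    """How many artifact sites to inject and their latent frequency ranges."""

    n_constant: int = 0
    n_ubiquitous: int = 0
    constant_af_range: tuple[float, float] = (0.1, 0.6)
    ubiquitous_af_range: tuple[float, float] = (0.05, 0.9)
    qual: float = 1000.0


@dataclass
class SimConfig:
    """Scenario description for one simulated experiment.

    Defaults follow the emulated study conditions: ~330 kb genome, mutation
    rate 2e-8 per site per replication, six replicates, 75 generations with
    six sampled time points, 1000x mean coverage, 1e-3 sequencing error.
    """

    genome_length: int = 330_611
    mu: float = 2e-8
    pop_size_profile: str = "constant"  # or "bottleneck"
    N_max: int = 100_000
    N_min: int = 100
    bottleneck_period: int = 15
    n_generations: int = 75
    sample_generations: tuple[int, ...] = (0, 15, 30, 45, 60, 75)
    selected_sites: Mapping[int, float] = field(default_factory=dict)
    init_freqs: Mapping[int, float] = field(default_factory=dict)
    depth_mean: float = 1000.0
    seq_error: float = 1e-3
    n_replicates: int = 6
    batch_map: Optional[Mapping[str, str]] = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    deterministic: bool = False
    max_classes: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if self.N_min > self.N_max:
            raise ValueError("N_min must be <= N_max")
        if self.pop_size_profile not in ("constant", "bottleneck"):
            raise ValueError("pop_size_profile must be constant|bottleneck")
        if any(
            g < 0 or g > self.n_generations for g in self.sample_generations
        ):
            raise ValueError("sample_generations must lie in [0, n_generations]")

    def replicate_ids(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replicates)]

    def batches(self) -> dict[str, str]:
        if self.batch_map is not None:
            return dict(self.batch_map)
        reps = self.replicate_ids()
        half = (len(reps) + 1) // 2
        return {
            rep: ("batchA" if i < half else "batchB")
            for i, rep in enumerate(reps)
        }

    def pop_size(self, generation: int) -> int:
        if self.pop_size_profile == "bottleneck":
            if generation > 0 and generation % self.bottleneck_period == 0:
                return self.N_min
        return self.N_max

    @property
    def treatment(self) -> Treatment:
        return (
            Treatment.STRONG_DEMOGRAPHY
            if self.pop_size_profile == "bottleneck"
            else Treatment.WEAK_DEMOGRAPHY
        )


@dataclass
class SimTruth:
    """Ground truth for a simulated table.

    ``sites``: DataFrame with pos, s, label (real_sweep / neutral /
    artifact_constant / artifact_ubiquitous) and origin_generation.
    ``trajectories``: per replicate, DataFrame of true frequencies indexed
    by position with one column per sampled generation.
    """

    sites: pd.DataFrame
    trajectories: dict[str, pd.DataFrame] = field(default_factory=dict)

    def label_of(self, pos: int) -> str:
        hit = self.sites.loc[self.sites["pos"] == pos, "label"]
        return hit.iloc[0] if len(hit) else "unknown"


def _wf_one_replicate(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Run one replicate; return (trajectory frame, site -> origin gen)."""
    N0 = cfg.pop_size(0)
    classes: dict[frozenset, float] = {}
    n_init = 0
    for pos, f0 in cfg.init_freqs.items():
        count = f0 * N0 if cfg.deterministic else round(f0 * N0)
        if count > 0:
            classes[frozenset({pos})] = count
            n_init += count
    classes[frozenset()] = N0 - n_init

    origin: dict[int, int] = {pos: 0 for pos in cfg.init_freqs}
    fitness_cache: dict[frozenset, float] = {}

    def fitness(cls: frozenset) -> float:
        w = fitness_cache.get(cls)
        if w is None:
            w = 1.0
            for pos in cls:
                w *= 1.0 + cfg.selected_sites.get(pos, 0.0)
            fitness_cache[cls] = w
        return w

    samples: dict[int, dict[int, float]] = {}

    def record(generation: int) -> None:
        if generation not in cfg.sample_generations:
            return
        total = sum(classes.values())
        freqs: dict[int, float] = {}
        for cls, count in classes.items():
            for pos in cls:
                freqs[pos] = freqs.get(pos, 0.0) + count / total
        samples[generation] = freqs

    record(0)
    for g in range(1, cfg.n_generations + 1):
        N_g = cfg.pop_size(g)
        keys = list(classes.keys())
        weights = np.array(
            [classes[c] * fitness(c) for c in keys], dtype=float
        )
        probs = weights / weights.sum()
        if cfg.deterministic:
            counts = probs * N_g
        else:
            counts = rng.multinomial(N_g, probs)
        classes = {
            c: n for c, n in zip(keys, counts) if n > 0
        }
        if not classes:  # extinct to numerical zero; keep the modal class
            classes = {keys[int(np.argmax(probs))]: N_g}
        if not cfg.deterministic and cfg.mu > 0:
            n_mut = rng.poisson(N_g * cfg.mu * cfg.genome_length)
            if n_mut:
                keys = list(classes.keys())
                counts_arr = np.array([classes[c] for c in keys], dtype=float)
                parent_idx = rng.choice(
                    len(keys), size=n_mut, p=counts_arr / counts_arr.sum()
                )
                positions = rng.integers(1, cfg.genome_length + 1, size=n_mut)
                for pos, pi in zip(positions, parent_idx):
                    parent = keys[pi]
                    if classes.get(parent, 0) < 1:
                        continue
                    child = parent | {int(pos)}
                    classes[parent] -= 1
                    if classes[parent] == 0:
                        del classes[parent]
                    classes[child] = classes.get(child, 0) + 1
                    origin.setdefault(int(pos), g)
        if len(classes) > cfg.max_classes:
            # merge the smallest classes into the wild-type background;
            # their private mutations are lost (logged via the count)
            ordered = sorted(classes.items(), key=lambda kv: kv[1])
            excess = len(classes) - cfg.max_classes
            lost = 0
            for cls, n in ordered[:excess]:
                lost += n
                del classes[cls]
            classes[frozenset()] = classes.get(frozenset(), 0) + lost
        record(g)

    all_pos = sorted({p for freqs in samples.values() for p in freqs})
    frame = pd.DataFrame(
        {
            g: [samples[g].get(p, 0.0) for p in all_pos]
            for g in sorted(samples)
        },
        index=pd.Index(all_pos, name="pos"),
    )
    return frame, origin


def simulate_wf(cfg: SimConfig) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Simulate all replicates; reproducible from ``cfg.seed``."""
    root = np.random.default_rng(cfg.seed)
    trajectories: dict[str, pd.DataFrame] = {}
    origins: dict[int, int] = {}
    for rep in cfg.replicate_ids():
        rng = np.random.default_rng(root.integers(2**31))
        frame, origin = _wf_one_replicate(cfg, rng)
        trajectories[rep] = frame
        for pos, g in origin.items():
            origins[pos] = min(origins.get(pos, g), g)
    all_pos = sorted(
        {int(p) for frame in trajectories.values() for p in frame.index}
    )
    sites = pd.DataFrame(
        {
            "pos": all_pos,
            "s": [cfg.selected_sites.get(p, 0.0) for p in all_pos],
            "label": [
                "real_sweep" if cfg.selected_sites.get(p, 0.0) > 0 else "neutral"
                for p in all_pos
            ],
            "origin_generation": [origins.get(p, -1) for p in all_pos],
        }
    )
    return trajectories, SimTruth(sites=sites, trajectories=trajectories)


def logistic_frequency(f0: float, s: float, generations: float) -> float:
    """Closed-form deterministic trajectory of a single selected variant
    under discrete generations with multiplicative fitness 1 + s:

        f(g) = f0 (1+s)^g / (1 - f0 + f0 (1+s)^g)

    (the familiar continuous-time logistic replaces (1+s)^g with e^{sg};
    the two agree to first order in s)."""
    w = f0 * (1.0 + s) ** generations
    return w / (1 - f0 + w)


def sample_poolseq(
    trajectories: Mapping[str, pd.DataFrame],
    cfg: SimConfig,
    genome: Optional[GenomeAnnotation] = None,
    seed: Optional[int] = None,
) -> VariantTable:
    """Turn true frequencies into a pooled-sequencing variant table.

    Sample days equal generations (the simulator's native clock); converting
    to wall-clock days is the analysis layer's concern. Simulated true sites
    get QUAL 1000.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    batches = cfg.batches()
    reps = list(trajectories.keys())
    all_pos = sorted(
        {int(p) for frame in trajectories.values() for p in frame.index}
    )
    samples = []
    freq_cols = []
    for rep in reps:
        frame = trajectories[rep]
        for g in sorted(frame.columns):
            samples.append(
                SampleMeta(
                    sample_id=f"{rep}_g{g}",
                    replicate_id=rep,
                    treatment=cfg.treatment,
                    day=int(g),
                    batch_id=batches.get(rep, "batchA"),
                )
            )
            col = frame.reindex(all_pos)[g].fillna(0.0).to_numpy()
            freq_cols.append(col)
    freqs = np.column_stack(freq_cols) if freq_cols else np.zeros((len(all_pos), 0))
    e = cfg.seq_error
    read_f = freqs * (1 - e) + (1 - freqs) * e
    depth = rng.poisson(cfg.depth_mean, size=read_f.shape)
    alt = rng.binomial(depth, read_f)
    ref = depth - alt

    sites = [
        _site_at(pos, genome, rng, qual=1000.0) for pos in all_pos
    ]
    return VariantTable(
        sites=sites,
        samples=samples,
        ref_counts=ref,
        alt_counts=alt,
        min_depth=10,
    )


def _site_at(
    pos: int,
    genome: Optional[GenomeAnnotation],
    rng: np.random.Generator,
    qual: float,
) -> VariantSite:
    if genome is not None and genome.sequence is not None:
        ref = genome.base_at(pos)
        contig = genome.contig
    else:
        ref = BASES[rng.integers(4)]
        contig = "sim1"
    alt = [b for b in BASES if b != ref][rng.integers(3)]
    return VariantSite(contig=contig, pos=pos, ref_base=ref, alt_base=alt, qual=qual)


def inject_artifacts(
    table: VariantTable,
    cfg: SimConfig,
    truth: Optional[SimTruth] = None,
    genome: Optional[GenomeAnnotation] = None,
    seed: Optional[int] = None,
) -> tuple[VariantTable, SimTruth]:
    """Append artifact sites to a table and record their truth labels.

    Constant artifacts hold one latent frequency per replicate across all of
    its time points; batch-wide polymorphic artifacts hold one intermediate
    latent frequency shared by every sample of a sequencing batch.
    """
    spec = cfg.artifact_spec
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    taken = {s.pos for s in table.sites}
    e = cfg.seq_error

    def fresh_pos() -> int:
        while True:
            pos = int(rng.integers(1, cfg.genome_length + 1))
            if pos not in taken:
                taken.add(pos)
                return pos

    rep_cols: dict[str, list[int]] = {}
    for j, s in enumerate(table.samples):
        rep_cols.setdefault(s.replicate_id, []).append(j)
    batch_cols = {}
    for j, s in enumerate(table.samples):
        batch_cols.setdefault(s.batch_id, []).append(j)

    new_sites, new_ref, new_alt, truth_rows = [], [], [], []

    def emit(pos: int, latent: dict[int, float], label: str) -> None:
        depth = rng.poisson(cfg.depth_mean, size=table.n_samples)
        f = np.array([latent[j] for j in range(table.n_samples)])
        read_f = f * (1 - e) + (1 - f) * e
        alt = rng.binomial(depth, read_f)
        new_sites.append(_site_at(pos, genome, rng, qual=spec.qual))
        new_ref.append(depth - alt)
        new_alt.append(alt)
        truth_rows.append(
            {"pos": pos, "s": 0.0, "label": label, "origin_generation": -1}
        )

    lo, hi = spec.constant_af_range
    for _ in range(spec.n_constant):
        latent = {}
        for cols in rep_cols.values():
            f = rng.uniform(lo, hi)
            for j in cols:
                latent[j] = f
        emit(fresh_pos(), latent, "artifact_constant")

    lo, hi = spec.ubiquitous_af_range
    for _ in range(spec.n_ubiquitous):
        latent = {}
        for cols in batch_cols.values():
            f = rng.uniform(lo, hi)
            for j in cols:
                latent[j] = f
        emit(fresh_pos(), latent, "artifact_ubiquitous")

    if not new_sites:
        out_truth = truth if truth is not None else SimTruth(
            sites=pd.DataFrame(columns=["pos", "s", "label", "origin_generation"])
        )
        return table, out_truth

    combined = VariantTable(
        sites=list(table.sites) + new_sites,
        samples=list(table.samples),
        ref_counts=np.vstack([table.ref_counts, np.array(new_ref)]),
        alt_counts=np.vstack([table.alt_counts, np.array(new_alt)]),
        min_depth=table.min_depth,
    )
    truth_sites = pd.DataFrame(
        truth_rows, columns=["pos", "s", "label", "origin_generation"]
    )
    if truth is not None:
        truth_sites = pd.concat([truth.sites, truth_sites], ignore_index=True)
        trajectories = truth.trajectories
    else:
        trajectories = {}
    return combined, SimTruth(sites=truth_sites, trajectories=trajectories)


def simulate_experiment(
    cfg: SimConfig, genome: Optional[GenomeAnnotation] = None
) -> tuple[VariantTable, SimTruth]:
    """Full pipeline input from one config: WF dynamics, pooled sequencing,
    artifact injection. Byte-reproducible from ``cfg.seed``."""
    trajectories, truth = simulate_wf(cfg)
    table = sample_poolseq(trajectories, cfg, genome=genome)
    return inject_artifacts(table, cfg, truth=truth, genome=genome)


# ---------------------------------------------------------------------------
# benchmark scenarios
# ---------------------------------------------------------------------------


def filter_benchmark_config(
    seed: int,
    n_sweeps: int = 20,
    n_constant: int = 20,
    n_ubiquitous: int = 20,
) -> SimConfig:
    """The standard filter-validation scenario: per replicate, ``n_sweeps``
    beneficial variants (s = 0.1) injected as standing variation at
    frequency 0.005, plus injected artifact sites of both kinds, at 1000x
    coverage over six sampled time points in six replicates."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(
        np.arange(1, 330_612), size=n_sweeps, replace=False
    )
    return SimConfig(
        mu=0.0,
        selected_sites={int(p): 0.1 for p in positions},
        init_freqs={int(p): 0.005 for p in positions},
        artifact_spec=ArtifactSpec(
            n_constant=n_constant, n_ubiquitous=n_ubiquitous
        ),
        seed=seed,
    )


def make_toy_genome(
    L: int,
    orf_spec: Sequence[tuple[int, int, str]],
    seed: int = 0,
    max_retries: int = 20,
) -> GenomeAnnotation:
    """Random genome of length ``L`` with valid ORFs at the given intervals.

    Each spec entry is (start, end, strand) with length a multiple of 3; the
    built ORF starts with ATG, ends with a stop codon, and contains no
    internal stop, reading through the reverse complement on '-'. Fails if
    overlapping ORF constraints cannot be satisfied.
    """
    rng = np.random.default_rng(seed)
    orfs = [
        ORF(name=f"orf{i + 1:03d}", segments=((start, end),), strand=strand)
        for i, (start, end, strand) in enumerate(orf_spec)
    ]
    for orf in orfs:
        if not orf.frame_ok:
            raise ValueError(f"{orf.name}: length {orf.length} not a multiple of 3")
        if orf.end > L:
            raise ValueError(f"{orf.name}: extends past genome length {L}")
    for _ in range(max_retries):
        seq = list("".join(rng.choice(list(BASES), size=L)))
        for orf in orfs:
            positions = orf.genomic_positions()
            n_codons = len(positions) // 3
            codons = ["ATG"]
            codons += [
                _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
                for _ in range(n_codons - 2)
            ]
            codons.append(_STOP_CODONS[rng.integers(3)])
            cds = "".join(codons)
            for base, pos in zip(cds, positions):
                seq[pos - 1] = (
                    base if orf.strand == "+" else base.translate(_COMPLEMENT)
                )
        genome = GenomeAnnotation(
            contig="toy1", genome_length=L, orfs=orfs, sequence="".join(seq)
        )
        if _validate_orfs(genome):
            return genome
    raise ValueError("could not satisfy overlapping ORF constraints")


def _validate_orfs(genome: GenomeAnnotation) -> bool:
    from .effects import CODON_TO_AA  # local import avoids a cycle

    for orf in genome.orfs:
        positions = orf.genomic_positions()
        if orf.strand == "+":
            cds = "".join(genome.base_at(p) for p in positions)
        else:
            cds = "".join(
                genome.base_at(p).translate(_COMPLEMENT) for p in positions
            )
        if not cds.startswith("ATG") or CODON_TO_AA[cds[-3:]] != "*":
            return False
        if any(
            CODON_TO_AA[cds[i : i + 3]] == "*" for i in range(0, len(cds) - 3, 3)
        ):
            return False
    return True


def random_orf_spec(
    L: int,
    n_orfs: int,
    seed: int = 0,
    min_codons: int = 10,
    max_codons: int = 100,
    max_tries: int = 200_000,
) -> list[tuple[int, int, str]]:
    """Non-overlapping random ORF intervals for :func:`make_toy_genome`."""
    rng = np.random.default_rng(seed)
    taken: list[tuple[int, int]] = []
    spec: list[tuple[int, int, str]] = []
    tries = 0
    while len(spec) < n_orfs:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_orfs} ORFs of {min_codons}-{max_codons} "
                f"codons in {L} bp"
            )
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        length = 3 * n_codons
        if length > L:
            continue
        start = int(rng.integers(1, L - length + 2))
        end = start + length - 1
        if any(s <= end + 1 and start <= e + 1 for s, e in taken):
            continue
        taken.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        spec.append((start, end, strand))
    spec.sort()
    return spec


__all__ = [
    "ArtifactSpec",
    "SimConfig",
    "SimTruth",
    "simulate_wf",
    "logistic_frequency",
    "sample_poolseq",
    "inject_artifacts",
    "simulate_experiment",
    "filter_benchmark_config",
    "make_toy_genome",
    "random_orf_spec",
]
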