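"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (read profiling, movement statistics,
qPCR quantification, differential crossing, EMS candidate filtering) consumes
only outputs that these generators can produce, so the whole pipeline is
testable without external downloads. All generators take an explicit ``seed``;
two runs with the same seed are byte-identical.

The generative models emulated:

* small-RNA libraries as a mixture of exact mature reads, 3'-trimmed reads,
  3'-tailed reads with U-biased non-templated tails (the signature of absent
  HEN1 2'-O-methylation), and end-shifted templated isoforms (isomiRs);
* a two-compartment emitter/recipient tissue design: the emitter compartment
  accumulates ``A * b`` (base abundance times a per-genotype biogenesis
  factor) and the recipient ``A * b * m`` with ``m`` the movement efficiency
  in [0, 1]; band intensities carry multiplicative log-normal noise;
* qPCR crossing-point values ``Cp = offset - log2(expression) + noise``;
* parent/EMS-pool variant tables with one homozygous causal EMS transition
  planted among shared and pool-private background variants;
* paired miRNA / transcript differential tables with an FDR column and a
  miRNA -> target map, with truth crossing counts recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    MatureAnnotation,
    ReferenceBundle,
    revcomp,
    to_dna,
)

NUCLEOTIDES = ("A", "C", "G", "T")

#: mature sequence of the amiRSUL reporter (RNA UUAAGUGUCACGGAAAUCCCU)
AMIRSUL_MATURE = "TTAAGTGTCACGGAAATCCCT"

READ_CLASSES = ("exact", "trim", "tail", "iso")


def _check_dist(dist: Mapping, name: str) -> None:
    total = sum(dist.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"{name} must sum to 1, got {total}")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass
class ModificationProfile:
    """Mixture weights and length/identity distributions for read classes."""

    p_exact: float = 0.85
    p_trim: float = 0.05
    p_tail: float = 0.05
    p_iso: float = 0.05
    trim_len_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    tail_len_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.07, 5: 0.03}
    )
    tail_alphabet_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 0.85, "A": 0.05, "C": 0.05, "G": 0.05}
    )
    iso_shift_dist: dict[int, float] = field(
        default_factory=lambda: {-2: 0.1, -1: 0.25, 0: 0.3, 1: 0.25, 2: 0.1}
    )

    def validate(self) -> None:
        probs = (self.p_exact, self.p_trim, self.p_tail, self.p_iso)
        if any(p < 0 for p in probs):
            raise ValueError("class probabilities must be non-negative")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"class probabilities must sum to 1, got {sum(probs)}")
        _check_dist(self.trim_len_dist, "trim_len_dist")
        _check_dist(self.tail_len_dist, "tail_len_dist")
        _check_dist(self.iso_shift_dist, "iso_shift_dist")
        w = self.tail_alphabet_weights
        if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("tail_alphabet_weights must be positive")
        bad = set(w) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"tail_alphabet_weights has non-DNA keys: {bad}")


def hen1_like_profile(p_tail: float = 0.40) -> ModificationProfile:
    """Profile mimicking a methylation-deficient (hen1-like) library: heavy
    U-tailing with accompanying trimming."""
    p_trim = 0.15
    p_iso = 0.05
    return ModificationProfile(
        p_exact=1.0 - p_tail - p_trim - p_iso,
        p_trim=p_trim,
        p_tail=p_tail,
        p_iso=p_iso,
    )


@dataclass
class TissueSimParams:
    """Two-compartment tissue experiment parameters.

    ``noise_sd`` is the standard deviation, on the log2 scale, of the
    multiplicative measurement noise applied to intensities.
    """

    base_abundance: float = 100.0
    noise_sd: float = 0.2
    n_replicates: int = 4
    loading_mean: float = 50.0

    def validate(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.loading_mean <= 0:
            raise ValueError("loading_mean must be positive")


@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype biogenesis factor and movement efficiency."""

    biogenesis: float = 1.0
    movement: float = 1.0
    is_reference: bool = False

    def validate(self, name: str) -> None:
        if self.biogenesis <= 0:
            raise ValueError(f"{name}: biogenesis factor must be positive")
        if not 0.0 <= self.movement <= 1.0:
            raise ValueError(f"{name}: movement efficiency must be in [0, 1]")


@dataclass(frozen=True)
class SimVariant:
    """A simulated SNV with allele fraction and effect-class annotation."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    allele_fraction: float
    effect: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class EmsSimSpec:
    """Layout of a simulated parent / bulked-mutant-pool resequencing pair."""

    n_background: int = 200
    n_pool_private: int = 20
    causal: SimVariant | None = None
    #: "near_half": pool-private AFs ~ Normal(0.5, 0.05) as expected for
    #: heterozygous, non-selected EMS background in a segregating pool;
    #: "uniform": AFs ~ Uniform(0, 1), useful for false-positive calibration.
    pool_private_af: str = "near_half"

    def validate(self) -> None:
        if self.n_background < 0 or self.n_pool_private < 0:
            raise ValueError("variant counts must be >= 0")
        if self.pool_private_af not in ("near_half", "uniform"):
            raise ValueError(f"unknown pool_private_af {self.pool_private_af!r}")


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def make_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (20, 22),
    genome_length: int = 2000,
    seed: int = 0,
    include_amirsul: bool = False,
    padding: int = 10,
    max_tries: int = 1000,
) -> ReferenceBundle:
    """Generate a random single-chromosome genome with ``n_mirnas`` mature
    miRNA loci placed non-overlapping (with ``padding`` nt of clearance).

    With ``include_amirsul=True`` the first locus carries the amiRSUL mature
    sequence (``AMIRSUL_MATURE``) instead of a random one; it is placed on the
    plus strand so the annotated mature equals the planted sequence.

    Raises ``RuntimeError`` if placement fails after ``max_tries`` attempts
    per locus.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    genome = list(_random_genome(rng, genome_length))
    occupied: list[tuple[int, int]] = []
    annotations: list[MatureAnnotation] = []
    chrom = "chr1"
    for i in range(n_mirnas):
        fixed_seq = AMIRSUL_MATURE if (include_amirsul and i == 0) else None
        length = len(fixed_seq) if fixed_seq else int(rng.integers(lo, hi + 1))
        placed = False
        for _ in range(max_tries):
            start = int(rng.integers(padding, genome_length - length - padding))
            end = start + length
            # padded spans [start-padding, end+padding) must stay disjoint
            if any(start - 2 * padding < e and s - 2 * padding < end
                   for s, e in occupied):
                continue
            strand = "+" if (fixed_seq or rng.random() < 0.5) else "-"
            if fixed_seq:
                genome[start:end] = list(fixed_seq)
                mature = fixed_seq
            else:
                mature = "".join(genome[start:end])
                if strand == "-":
                    mature = revcomp(mature)
            name = "amiRSUL" if fixed_seq else f"mir{i + 1:03d}"
            annotations.append(
                MatureAnnotation(name, chrom, start, end, strand, mature)
            )
            occupied.append((start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place locus {i + 1}/{n_mirnas} after {max_tries} tries; "
                "genome too short"
            )
    bundle = ReferenceBundle("".join(genome), annotations, chrom=chrom)
    bundle.validate(padding=padding)
    return bundle


def make_amirsul_reference(genome_length: int = 400, seed: int = 0) -> ReferenceBundle:
    """Single-locus fixture carrying the amiRSUL mature sequence."""
    return make_reference(
        1, genome_length=genome_length, seed=seed, include_amirsul=True
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _truncated_dist(dist: Mapping[int, float], max_val: int) -> dict[int, float]:
    kept = {k: v for k, v in dist.items() if k <= max_val and v > 0}
    total = sum(kept.values())
    if total <= 0:
        return {}
    return {k: v / total for k, v in kept.items()}


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs))]


def _make_tail(
    rng: np.random.Generator,
    profile: ModificationProfile,
    length: int,
    forbidden_first: str | None,
) -> str:
    """Draw a non-templated tail; the first base is resampled away from the
    next templated genomic base so tailed reads never mimic templated
    extensions."""
    weights = dict(profile.tail_alphabet_weights)
    first_weights = {
        k: v for k, v in weights.items() if k != forbidden_first and v > 0
    }
    if not first_weights:  # degenerate single-letter alphabet: fall back
        first_weights = {k: v for k, v in weights.items() if v > 0}
    first_total = sum(first_weights.values())
    bases = [str(_draw(rng, {k: v / first_total for k, v in first_weights.items()}))]
    norm = {k: v / sum(weights.values()) for k, v in weights.items() if v > 0}
    for _ in range(length - 1):
        bases.append(str(_draw(rng, norm)))
    return "".join(bases)


def _make_iso_read(
    rng: np.random.Generator,
    ref: ReferenceBundle,
    ann: MatureAnnotation,
    profile: ModificationProfile,
    max_tries: int = 200,
) -> tuple[str, int, int] | None:
    """Templated end-shifted isoform: perfect genomic match nested in the
    locus +/- 5 nt, length mature +/- 1, not identical to the mature.

    Returns ``(read, five_prime_shift, length_offset)``.
    """
    L = ann.length
    for _ in range(max_tries):
        s = int(_draw(rng, profile.iso_shift_dist))  # 5' shift, miRNA orientation
        d = int(rng.integers(-1, 2))  # length offset
        if (s, d) == (0, 0):
            continue
        if s < -5 or s + d > 5:
            continue
        if ann.strand == "+":
            start = ann.start + s
            end = start + L + d
            if start < 0 or end > len(ref.genome):
                continue
            read = ref.genome[start:end]
        else:
            end = ann.end - s
            start = end - (L + d)
            if start < 0 or end > len(ref.genome):
                continue
            read = revcomp(ref.genome[start:end])
        if read != ann.mature_seq:
            return read, s, d
    return None


def log_uniform_abundances(
    mirna_ids: Sequence[str],
    seed: int,
    low: float = 1.0,
    high: float = 1000.0,
) -> dict[str, float]:
    """Relative abundances drawn log-uniformly on [low, high]; the default
    distribution across miRNAs in simulated libraries."""
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.uniform(np.log(low), np.log(high), size=len(mirna_ids)))
    return dict(zip(mirna_ids, vals))


def simulate_reads(
    ref: ReferenceBundle,
    per_mirna_abundance: Mapping[str, float],
    profile: ModificationProfile,
    depth: int,
    seed: int,
    adapter: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Simulate ``depth`` small-RNA reads from the annotated loci.

    Reads are allocated to miRNAs multinomially according to
    ``per_mirna_abundance`` and each read is assigned a modification class
    (exact / trim / tail / iso) from ``profile``. Trim lengths are truncated so
    trimmed reads stay >= 18 nt, and tail lengths so tailed reads stay <= 26
    nt, keeping every modified read inside the anchored counting window; when
    a mature is so short that no trim length is valid the read falls back to
    the exact class (recorded truthfully).

    Returns ``(reads, truth)`` where ``reads`` are DNA sequences (with
    ``adapter`` appended when given) and ``truth`` has one row per read with
    columns read_id, mirna_id, true_class, insert and
    ``expected_anchor_class`` — the label an exact anchored classifier should
    assign at this locus (isoforms whose 5' end is unshifted are templated
    3'-end variants and legitimately land in the shorter/longer buckets;
    5'-shifted isoforms are unanchored).
    """
    profile.validate()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    ann_by_id = {a.id: a for a in ref.annotations}
    unknown = set(per_mirna_abundance) - set(ann_by_id)
    if unknown:
        raise ValueError(f"abundances given for unannotated miRNAs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    rows: list[tuple[str, str, str, str, str]] = []
    truth_cols = ["read_id", "mirna_id", "true_class", "insert",
                  "expected_anchor_class"]
    if depth == 0 or not per_mirna_abundance:
        return reads, pd.DataFrame(rows, columns=truth_cols)

    ids = sorted(per_mirna_abundance)
    weights = np.array([per_mirna_abundance[i] for i in ids], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("abundances must be positive")
    counts = rng.multinomial(depth, weights / weights.sum())
    class_p = np.array([profile.p_exact, profile.p_trim, profile.p_tail, profile.p_iso])

    k = 0
    for mirna_id, n_reads in zip(ids, counts):
        ann = ann_by_id[mirna_id]
        L = ann.length
        trim_dist = _truncated_dist(profile.trim_len_dist, L - 18)
        tail_dist = _truncated_dist(profile.tail_len_dist, 26 - L)
        forbidden = ref.next_templated_base(ann)
        for _ in range(int(n_reads)):
            cls = READ_CLASSES[int(rng.choice(4, p=class_p))]
            if cls == "trim" and not trim_dist:
                cls = "exact"
            if cls == "tail" and not tail_dist:
                cls = "exact"
            if cls == "exact":
                insert, anchor = ann.mature_seq, "exact"
            elif cls == "trim":
                t = int(_draw(rng, trim_dist))
                insert, anchor = ann.mature_seq[:-t], "shorter"
            elif cls == "tail":
                t = int(_draw(rng, tail_dist))
                insert = ann.mature_seq + _make_tail(rng, profile, t, forbidden)
                anchor = "longer"
            else:
                iso = _make_iso_read(rng, ref, ann, profile)
                if iso is None:
                    cls, insert, anchor = "exact", ann.mature_seq, "exact"
                else:
                    insert, s, d = iso
                    if s != 0:
                        anchor = "unanchored"
                    else:
                        anchor = "shorter" if d < 0 else "longer"
            read_id = f"read{k:07d}"
            k += 1
            reads.append(insert + adapter if adapter else insert)
            rows.append((read_id, mirna_id, cls, insert, anchor))
    return reads, pd.DataFrame(rows, columns=truth_cols)


# ---------------------------------------------------------------------------
# tissue experiment
# ---------------------------------------------------------------------------

def simulate_tissue_experiment(
    design: Mapping[str, GenotypeParams],
    params: TissueSimParams,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an emitter/recipient band-intensity table.

    One row per (genotype, tissue, replicate) with a target and a loading
    intensity. The lane scale factor (loading noise) multiplies both target
    and loading intensity, so loading normalization removes it exactly;
    target-specific noise of ``noise_sd`` (log2) remains. With
    ``noise_sd = 0``, recipient/emitter ratios equal the genotype's movement
    efficiency exactly.

    Returns ``(table, truth)``; ``truth`` records per-genotype expected
    emitter/recipient levels and the movement efficiency.
    """
    params.validate()
    if not design:
        raise ValueError("design must contain at least one genotype")
    if not any(g.is_reference for g in design.values()):
        raise ValueError("at least one genotype must be flagged as reference")
    for name, g in design.items():
        g.validate(name)
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for genotype in design:
        g = design[genotype]
        expected = {
            "emitter": params.base_abundance * g.biogenesis,
            "recipient": params.base_abundance * g.biogenesis * g.movement,
        }
        truth_rows.append(
            (genotype, g.biogenesis, g.movement, expected["emitter"],
             expected["recipient"], g.is_reference)
        )
        for rep in range(1, params.n_replicates + 1):
            for tissue in ("emitter", "recipient"):
                lane = 2.0 ** (params.noise_sd * rng.standard_normal())
                meas = 2.0 ** (params.noise_sd * rng.standard_normal())
                rows.append(
                    {
                        "sample_id": f"{genotype}_{tissue}_r{rep}",
                        "genotype": genotype,
                        "tissue": tissue,
                        "replicate": rep,
                        "target_intensity": expected[tissue] * lane * meas,
                        "loading_intensity": params.loading_mean * lane,
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["genotype", "biogenesis", "movement", "expected_emitter",
                 "expected_recipient", "is_reference"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    expression_table: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    offset: float = 30.0,
) -> pd.DataFrame:
    """Invert the 2^-dCp quantification: emit crossing-point values from known
    expression levels.

    ``expression_table`` needs columns sample_id, target, condition,
    expression, is_reference; reference targets are generated from their own
    stated expressions. ``Cp = offset - log2(expression) + N(0, noise_sd)``.
    """
    required = {"sample_id", "target", "condition", "expression", "is_reference"}
    missing = required - set(expression_table.columns)
    if missing:
        raise ValueError(f"expression_table missing columns: {sorted(missing)}")
    expr = expression_table["expression"].to_numpy(dtype=float)
    if np.any(expr <= 0):
        raise ValueError("expressions must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(expr)) if noise_sd > 0 else 0.0
    out = expression_table[
        ["sample_id", "target", "condition", "is_reference"]
    ].copy()
    out["Cp"] = offset - np.log2(expr) + noise
    return out[["sample_id", "target", "condition", "Cp", "is_reference"]]


# ---------------------------------------------------------------------------
# EMS experiment
# ---------------------------------------------------------------------------

EFFECT_CLASSES = ("missense", "splice", "synonymous", "intergenic", "other")
_EMS_ALTS = {"G": "A", "C": "T"}


def _random_variant(
    rng: np.random.Generator,
    ref: ReferenceBundle,
    used: set[int],
    af: float,
    effect: str | None = None,
) -> SimVariant:
    while True:
        pos0 = int(rng.integers(0, len(ref.genome)))
        if pos0 in used:
            continue
        used.add(pos0)
        break
    ref_base = ref.genome[pos0]
    alt = str(rng.choice([n for n in NUCLEOTIDES if n != ref_base]))
    eff = effect if effect else str(rng.choice(EFFECT_CLASSES))
    return SimVariant(ref.chrom, pos0 + 1, ref_base, alt, float(af), eff)


def simulate_ems_experiment(
    ref: ReferenceBundle,
    spec: EmsSimSpec,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, SimVariant]:
    """Simulate parent and bulked-mutant-pool variant tables.

    Shared background variants appear identically in both tables; pool-private
    background variants carry allele fractions around 0.5 (segregating,
    non-selected) or uniform on (0, 1) depending on ``spec.pool_private_af``;
    the causal variant is a homozygous (AF 1.0) EMS-type transition with a
    missense or splice effect, present only in the pool.

    Returns ``(parent_table, pool_table, causal)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    used: set[int] = set()

    if spec.causal is None:
        # plant a G->A or C->T transition at a genomic G/C
        while True:
            pos0 = int(rng.integers(0, len(ref.genome)))
            if pos0 in used or ref.genome[pos0] not in _EMS_ALTS:
                continue
            used.add(pos0)
            base = ref.genome[pos0]
            effect = str(rng.choice(["missense", "splice"]))
            causal = SimVariant(ref.chrom, pos0 + 1, base, _EMS_ALTS[base], 1.0, effect)
            break
    else:
        causal = spec.causal
        used.add(causal.pos - 1)

    shared = [
        _random_variant(rng, ref, used, af=float(np.clip(rng.uniform(), 0.0, 1.0)))
        for _ in range(spec.n_background)
    ]
    private = []
    for _ in range(spec.n_pool_private):
        if spec.pool_private_af == "near_half":
            af = float(np.clip(rng.normal(0.5, 0.05), 0.0, 1.0))
        else:
            af = float(rng.uniform())
        private.append(_random_variant(rng, ref, used, af=af))

    def _frame(variants: list[SimVariant]) -> pd.DataFrame:
        rows = sorted(variants, key=lambda v: (v.chrom, v.pos))
        return pd.DataFrame(
            [
                (v.chrom, v.pos, v.ref, v.alt, v.allele_fraction, v.effect)
                for v in rows
            ],
            columns=["chrom", "pos", "ref", "alt", "allele_fraction", "effect"],
        )

    parent = _frame(shared)
    pool = _frame(shared + private + [causal])
    return parent, pool, causal


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

def simulate_de_tables(
    n_mirnas: int = 50,
    n_transcripts: int = 500,
    target_map_density: float = 0.01,
    frac_mirna_down: float = 0.1,
    frac_target_up: float = 0.1,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Simulate miRNA and transcript differential tables plus a target map.

    Truly differential features receive FDR values strictly below ``alpha``
    and mean shifts consistent with their direction; non-differential features
    receive FDR in [alpha, 1]. Returns
    ``(mirna_table, transcript_table, target_map, truth_counts)`` where
    ``truth_counts`` holds the crossing counts implied by construction
    (n_targets_considered / n_targets_up / n_targets_up_of_down_mirnas).
    """
    for name, frac in (("target_map_density", target_map_density),
                       ("frac_mirna_down", frac_mirna_down),
                       ("frac_target_up", frac_target_up)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mirna_ids = [f"miR{i + 1:03d}" for i in range(n_mirnas)]
    tx_ids = [f"TX{i + 1:05d}" for i in range(n_transcripts)]

    def _table(ids: list[str], frac_flag: float, direction: str) -> pd.DataFrame:
        n = len(ids)
        n_flag = int(round(frac_flag * n))
        flagged = np.zeros(n, dtype=bool)
        flagged[rng.choice(n, size=n_flag, replace=False)] = True
        base = np.exp(rng.uniform(np.log(5.0), np.log(5000.0), size=n))
        fold = rng.uniform(1.5, 4.0, size=n)
        mean_a = base
        mean_b = base.copy()
        if direction == "down":
            mean_b[flagged] = base[flagged] / fold[flagged]
        else:
            mean_b[flagged] = base[flagged] * fold[flagged]
        fdr = rng.uniform(alpha, 1.0, size=n)
        fdr[flagged] = rng.uniform(0.0, alpha * 0.98, size=n_flag)
        return pd.DataFrame(
            {"feature_id": ids, "mean_a": mean_a, "mean_b": mean_b,
             "fdr": fdr, "true_flagged": flagged}
        )

    mirna_tab = _table(mirna_ids, frac_mirna_down, "down")
    tx_tab = _table(tx_ids, frac_target_up, "up")

    pair_mask = rng.random((n_mirnas, n_transcripts)) < target_map_density
    pairs = [
        (mirna_ids[i], tx_ids[j])
        for i, j in zip(*np.nonzero(pair_mask))
    ]
    target_map = pd.DataFrame(pairs, columns=["mirna_id", "transcript_id"])

    mapped_tx = set(target_map["transcript_id"])
    down_mirnas = set(mirna_tab.loc[mirna_tab["true_flagged"], "feature_id"])
    up_tx = set(tx_tab.loc[tx_tab["true_flagged"], "feature_id"]) & mapped_tx
    tx_of_down = set(
        target_map.loc[target_map["mirna_id"].isin(down_mirnas), "transcript_id"]
    )
    truth = {
        "n_targets_considered": len(mapped_tx),
        "n_targets_up": len(up_tx),
        "n_targets_up_of_down_mirnas": len(up_tx & tx_of_down),
    }
    return mirna_tab, tx_tab, target_map, truth
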