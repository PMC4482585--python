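"""Ground-truthed synthetic GBS and amplicon data for tetraploid populations.

This module emulates the data structure of a reduced-representation
(ApeKI GBS) survey of two heterogeneous autotetraploid populations - a base
synthetic cultivar and a derivative obtained by recurrent selection - plus an
amplicon re-sequencing panel used to validate genotype calls.  Everything
downstream (tag discovery, calling, filtering, validation, PCA) can therefore
be tested against known truth without any external download.

Model summary
-------------
* Populations: random-mating autotetraploid (polysomic) inheritance with
  independent loci; per-locus A1 frequency ``p`` gives dosage ~ Binomial(4, p).
  Recurrent selection is emulated as a deterministic frequency shift at a
  marked subset of loci.
* Tags: each locus is a reciprocal pair of 64-base tags beginning with the
  ApeKI half-site remnant ``CAGC`` and differing at exactly one position.
* Depth: reads per sample-locus ~ Poisson with log-normal sample and locus
  multipliers (heavy-tailed, as observed in real GBS runs), plus a dropout
  probability; alleles whose restriction site is flagged polymorphic yield
  zero reads (allele dropout).
* Errors: GBS reads receive per-base substitutions; amplicon reads receive
  homopolymer indels (the signature artefact of pyrosequencing).

Seeding: one master seed on the population model; each generator stage
derives a child seed by a fixed documented offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gcall

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: ApeKI half-site remnant at the start of every tag.
CUT_REMNANT = "CAGC"
TAG_LEN = 64

# Child-seed offsets from the master seed (documented output metadata).
GBS_SEED_OFFSET = 1
AMPLICON_SEED_OFFSET = 2
DESIGN_SEED_OFFSET = 3


# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class PopulationModel:
    """Two populations of autotetraploid samples with per-locus A1 frequencies.

    ``base_allele_freqs`` applies to population 1; at ``shifted_fraction`` of
    loci the frequency in population 2 is moved by ``shift_magnitude``
    (random direction, clamped to [0.01, 0.99]).
    """

    n_loci: int
    n_samples_per_pop: int
    base_allele_freqs: np.ndarray
    shifted_fraction: float = 0.0
    shift_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.n_samples_per_pop <= 0:
            raise ValueError("n_samples_per_pop must be positive")
        freqs = np.asarray(self.base_allele_freqs, dtype=float)
        if freqs.shape != (self.n_loci,):
            raise ValueError("base_allele_freqs must have length n_loci")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("allele frequencies must be strictly in (0, 1)")
        if not 0.0 <= self.shifted_fraction <= 1.0:
            raise ValueError("shifted_fraction must be in [0, 1]")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be non-negative")
        object.__setattr__(self, "base_allele_freqs", freqs)

    @classmethod
    def random(cls, n_loci, n_samples_per_pop, seed, freq_low=0.1, freq_high=0.9,
               shifted_fraction=0.0, shift_magnitude=0.0):
        """Model with A1 frequencies ~ Uniform(freq_low, freq_high).

        The broad uniform default mimics a heterogeneous outcrossed cultivar
        in which most discovered SNPs segregate at intermediate frequency.
        """
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(freq_low, freq_high, n_loci)
        return cls(n_loci=n_loci, n_samples_per_pop=n_samples_per_pop,
                   base_allele_freqs=freqs, shifted_fraction=shifted_fraction,
                   shift_magnitude=shift_magnitude, seed=seed)


@dataclass(frozen=True)
class DepthModel:
    """Reads per sample-locus ~ Poisson(mean * S_i * L_j), with log-normal
    sample (S) and locus (L) multipliers of unit mean, zeroed with
    probability ``dropout_prob``."""

    mean_depth: float = 15.0
    sample_effect_sd: float = 0.4
    locus_effect_sd: float = 0.7
    dropout_prob: float = 0.05

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.sample_effect_sd < 0 or self.locus_effect_sd < 0:
            raise ValueError("effect spreads must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error rates: per-base substitutions on GBS reads,
    per-homopolymer-run indels on amplicon reads."""

    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.001

    def __post_init__(self):
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0.0 <= r <= 0.1:
                raise ValueError("error rates must be in [0, 0.1]")


@dataclass
class TruthSet:
    """Complete ground truth for one simulated experiment."""

    samples: list[str]
    populations: np.ndarray        # population label per sample
    dosage: np.ndarray             # (n_samples, n_loci) A1 copy number 0..4
    a1: list[str]                  # 64-base tag per locus (A1)
    a2: list[str]
    snp_offset: np.ndarray         # 0-based differing position per locus
    site_intact: np.ndarray        # (n_loci, 2) bool, restriction site per allele
    shifted: np.ndarray            # bool per locus
    freqs: np.ndarray              # (2, n_loci) per-population A1 frequency
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.a1)

    @property
    def locus_ids(self) -> list[str]:
        return [f"TP{i + 1:05d}" for i in range(self.n_loci)]

    def true_diploid_codes(self) -> pd.DataFrame:
        """Loci x samples matrix of true diploid codes (dosage collapsed)."""
        d = self.dosage.T
        codes = np.full(d.shape, gcall.HET, dtype=np.int8)
        codes[d == 0] = gcall.HOM_A2
        codes[d == 4] = gcall.HOM_A1
        return pd.DataFrame(codes, index=self.locus_ids, columns=self.samples)


# --------------------------------------------------------------------------
# population simulation


def _random_tags(rng: np.random.Generator, n_loci: int):
    """Unique 64-base tag pairs starting with the cut-site remnant and
    differing at exactly one post-remnant position."""
    a1, a2, offsets = [], [], []
    seen: set[str] = set()
    body_len = TAG_LEN - len(CUT_REMNANT)
    while len(a1) < n_loci:
        body = "".join(_BASES[i] for i in rng.integers(0, 4, body_len))
        tag1 = CUT_REMNANT + body
        off = int(rng.integers(len(CUT_REMNANT), TAG_LEN))
        shift = int(rng.integers(1, 4))
        new_base = _BASES[(_BASE_IDX[tag1[off]] + shift) % 4]
        tag2 = tag1[:off] + new_base + tag1[off + 1:]
        if tag1 in seen or tag2 in seen:
            continue
        seen.update((tag1, tag2))
        a1.append(tag1)
        a2.append(tag2)
        offsets.append(off)
    return a1, a2, np.asarray(offsets)


def simulate_population(model: PopulationModel,
                        site_polymorphism_rate: float = 0.0) -> TruthSet:
    """Draw a ground-truth experiment from a population model.

    Deterministic for a fixed ``model.seed``.  ``site_polymorphism_rate`` is
    the per-allele probability that the restriction site of that allele is
    disrupted (the allele then yields no GBS reads).
    """
    rng = np.random.default_rng(model.seed)
    n_loci, n_per = model.n_loci, model.n_samples_per_pop

    n_shifted = int(round(model.shifted_fraction * n_loci))
    shifted = np.zeros(n_loci, dtype=bool)
    if n_shifted:
        shifted[rng.choice(n_loci, n_shifted, replace=False)] = True
    p1 = model.base_allele_freqs
    p2 = p1.copy()
    if n_shifted:
        sign = rng.choice([-1.0, 1.0], n_shifted)
        p2[shifted] = np.clip(p1[shifted] + sign * model.shift_magnitude,
                              0.01, 0.99)
    freqs = np.vstack([p1, p2])

    dosage = np.empty((2 * n_per, n_loci), dtype=np.int8)
    dosage[:n_per] = rng.binomial(4, p1, size=(n_per, n_loci))
    dosage[n_per:] = rng.binomial(4, p2, size=(n_per, n_loci))

    a1, a2, offsets = _random_tags(rng, n_loci)
    site_intact = rng.random((n_loci, 2)) >= site_polymorphism_rate

    samples = [f"ATF0-{i + 1:02d}" for i in range(n_per)] + \
              [f"ATF5-{i + 1:02d}" for i in range(n_per)]
    populations = np.array(["ATF0"] * n_per + ["ATF5"] * n_per)
    return TruthSet(samples=samples, populations=populations, dosage=dosage,
                    a1=a1, a2=a2, snp_offset=offsets, site_intact=site_intact,
                    shifted=shifted, freqs=freqs, seed=model.seed)


# --------------------------------------------------------------------------
# GBS reads


def default_barcodes(n: int, length: int = 6) -> list[str]:
    """A deterministic prefix-free barcode set (all barcodes equal length)."""
    if n > 4 ** length:
        raise ValueError("not enough barcodes of this length")
    stride = max(1, 4 ** length // n)
    combos = itertools.islice(itertools.product(_BASES, repeat=length),
                              0, n * stride, stride)
    return ["".join(c) for c in combos][:n]


def _conditional_nsub_pmf(length: int, rate: float) -> np.ndarray:
    """P(k substitutions | >= 1) for k = 1..length, binomial per-base model."""
    k = np.arange(1, length + 1)
    pmf = stats.binom.pmf(k, length, rate)
    return pmf / pmf.sum()


def _substitute(seq: str, positions, shifts) -> str:
    b = list(seq)
    for p, s in zip(positions, shifts):
        b[p] = _BASES[(_BASE_IDX[b[p]] + s) % 4]
    return "".join(b)


@dataclass
class GbsReadSet:
    """Barcoded GBS reads (grouped by identical sequence) plus emitted-read
    truth tables.  ``rc1``/``rc2`` count reads emitted per allele, including
    reads later mutated by sequencing error."""

    groups: list[tuple[str, int]]
    rc1: pd.DataFrame               # loci x samples
    rc2: pd.DataFrame
    barcodes: dict[str, str]
    populations: dict[str, str]

    @property
    def n_reads(self) -> int:
        return sum(c for _, c in self.groups)

    def reads_per_sample(self) -> pd.Series:
        return (self.rc1.sum(axis=0) + self.rc2.sum(axis=0)).astype(int)

    def iter_sequences(self):
        for seq, count in self.groups:
            for _ in range(count):
                yield seq

    def write_fastq(self, path, quality_char: str = "I") -> None:
        """Phred+33 FASTQ with constant quality."""
        with open(path, "w") as fh:
            i = 0
            for seq, count in self.groups:
                q = quality_char * len(seq)
                for _ in range(count):
                    fh.write(f"@sim_{i}\n{seq}\n+\n{q}\n")
                    i += 1

    def write_key(self, path) -> None:
        """Barcode key TSV: sample_id, population, barcode."""
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\tbarcode\n")
            for s, bc in self.barcodes.items():
                fh.write(f"{s}\t{self.populations[s]}\t{bc}\n")


def sample_gbs_reads(truth: TruthSet, depth: DepthModel, err: ErrorModel,
                     barcodes: list[str] | None = None,
                     rng: np.random.Generator | None = None) -> GbsReadSet:
    """Emit barcoded single-end GBS reads for every sample-locus.

    Read = barcode + 64-base tag (tag starts with the cut-site remnant).
    Per sample-locus the read total is drawn from the depth model and
    partitioned Binomial(n, d/4) between alleles given true dosage d; alleles
    with a disrupted restriction site yield zero reads.  Substitution errors
    are applied per base over the whole tag.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + GBS_SEED_OFFSET)
    n_s, n_l = truth.dosage.shape
    if barcodes is None:
        barcodes = default_barcodes(n_s)
    if len(barcodes) != n_s:
        raise ValueError("need one barcode per sample")
    if len(set(barcodes)) != n_s:
        raise ValueError("duplicate barcodes")

    s_sd, l_sd = depth.sample_effect_sd, depth.locus_effect_sd
    s_mult = np.exp(rng.normal(-s_sd ** 2 / 2, s_sd, n_s))
    l_mult = np.exp(rng.normal(-l_sd ** 2 / 2, l_sd, n_l))
    lam = depth.mean_depth * s_mult[:, None] * l_mult[None, :]
    n = rng.poisson(lam)
    if depth.dropout_prob > 0:
        n[rng.random(n.shape) < depth.dropout_prob] = 0

    k1 = rng.binomial(n, truth.dosage / 4.0)
    k2 = n - k1
    k1[:, ~truth.site_intact[:, 0]] = 0
    k2[:, ~truth.site_intact[:, 1]] = 0

    rate = err.substitution_rate
    p_any = 1.0 - (1.0 - rate) ** TAG_LEN if rate > 0 else 0.0
    cond_pmf = _conditional_nsub_pmf(TAG_LEN, rate) if rate > 0 else None

    groups: list[tuple[str, int]] = []
    tags = (truth.a1, truth.a2)
    for allele, k in enumerate((k1, k2)):
        n_err = rng.binomial(k, p_any) if p_any > 0 else np.zeros_like(k)
        si, li = np.nonzero(k)
        # draw all substitution counts for this allele's error reads at once
        m_tot = int(n_err[si, li].sum())
        if m_tot:
            nsubs = rng.choice(np.arange(1, TAG_LEN + 1), size=m_tot, p=cond_pmf)
        pos_err = 0
        for i, j in zip(si, li):
            read = barcodes[i] + tags[allele][j]
            clean = int(k[i, j] - n_err[i, j])
            if clean:
                groups.append((read, clean))
            for _ in range(int(n_err[i, j])):
                ns = int(nsubs[pos_err]); pos_err += 1
                positions = rng.choice(TAG_LEN, ns, replace=False) + len(barcodes[i])
                shifts = rng.integers(1, 4, ns)
                groups.append((_substitute(read, positions, shifts), 1))

    locus_ids = truth.locus_ids
    rc1 = pd.DataFrame(k1.T, index=locus_ids, columns=truth.samples)
    rc2 = pd.DataFrame(k2.T, index=locus_ids, columns=truth.samples)
    return GbsReadSet(groups=groups, rc1=rc1, rc2=rc2,
                      barcodes=dict(zip(truth.samples, barcodes)),
                      populations=dict(zip(truth.samples, truth.populations)))


# --------------------------------------------------------------------------
# amplicon panel


@dataclass(frozen=True)
class HaplotypeSpec:
    """A haplotype = consensus + substitutions at ``variants`` (0-based)."""

    variants: tuple[tuple[int, str], ...]
    gbs_allele: int  # 1 or 2: which GBS allele this haplotype carries

    def sequence(self, consensus: str) -> str:
        b = list(consensus)
        for pos, base in self.variants:
            b[pos] = base
        return "".join(b)


@dataclass
class AmpliconDesign:
    """One amplicon: consensus carrying the A1 tag, defined haplotypes and
    the per-sample phase (four haplotype copies per tetraploid sample)."""

    amplicon_id: str
    consensus: str
    locus_index: int
    tag_start: int
    haplotypes: list[HaplotypeSpec]
    per_sample_copies: dict[str, tuple[int, int, int, int]]
    window_length: int = 400


def design_amplicons(truth: TruthSet, loci: list[int], samples: list[str],
                     length: int = 550, window_length: int = 400,
                     n_extra_haplotypes: int = 2,
                     rng: np.random.Generator | None = None) -> list[AmpliconDesign]:
    """Build a single-locus amplicon panel covering ``loci`` for ``samples``.

    Each amplicon embeds the locus's A1 tag in a random consensus.  The
    haplotype set always contains the plain A1 and A2 haplotypes plus
    ``n_extra_haplotypes`` variants carrying 1-3 extra substitutions in the
    window but outside the 64-base tag (so every haplotype still matches one
    GBS allele exactly).  Each sample's four copies are drawn consistent with
    its true dosage.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + DESIGN_SEED_OFFSET)
    if length < 420:
        raise ValueError("amplicon length must be >= 420")
    sample_idx = {s: i for i, s in enumerate(truth.samples)}
    designs = []
    for locus in loci:
        cons = list("".join(_BASES[i] for i in rng.integers(0, 4, length)))
        tag_start = int(rng.integers(20, window_length - TAG_LEN - 20))
        cons[tag_start:tag_start + TAG_LEN] = truth.a1[locus]
        consensus = "".join(cons)
        snp_pos = tag_start + int(truth.snp_offset[locus])
        a2_base = truth.a2[locus][int(truth.snp_offset[locus])]

        haps = [HaplotypeSpec((), 1), HaplotypeSpec(((snp_pos, a2_base),), 2)]
        tag_range = range(tag_start, tag_start + TAG_LEN)
        candidates = [p for p in range(window_length) if p not in tag_range]
        for _ in range(n_extra_haplotypes):
            base_allele = int(rng.integers(1, 3))
            n_var = int(rng.integers(1, 4))
            pos = rng.choice(candidates, n_var, replace=False)
            variants = []
            if base_allele == 2:
                variants.append((snp_pos, a2_base))
            for p in sorted(int(x) for x in pos):
                shift = int(rng.integers(1, 4))
                variants.append(
                    (p, _BASES[(_BASE_IDX[consensus[p]] + shift) % 4]))
            haps.append(HaplotypeSpec(tuple(variants), base_allele))

        a1_haps = [i for i, h in enumerate(haps) if h.gbs_allele == 1]
        a2_haps = [i for i, h in enumerate(haps) if h.gbs_allele == 2]
        copies = {}
        for s in samples:
            d = int(truth.dosage[sample_idx[s], locus])
            chosen = [int(rng.choice(a1_haps)) for _ in range(d)] + \
                     [int(rng.choice(a2_haps)) for _ in range(4 - d)]
            copies[s] = tuple(chosen)
        designs.append(AmpliconDesign(
            amplicon_id=f"AMP_{truth.locus_ids[locus]}", consensus=consensus,
            locus_index=locus, tag_start=tag_start, haplotypes=haps,
            per_sample_copies=copies, window_length=window_length))
    return designs


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of mononucleotide runs of at least ``min_len``."""
    runs, i = [], 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


@dataclass
class AmpliconReadSet:
    """Per sample x amplicon read groups and the emitted per-haplotype truth."""

    reads: dict[tuple[str, str], list[tuple[str, int]]]
    hap_counts: dict[tuple[str, str], np.ndarray]

    def sample_reads(self, sample: str, amplicon_id: str) -> list[tuple[str, int]]:
        return self.reads[(sample, amplicon_id)]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            i = 0
            for (sample, amp), groups in sorted(self.reads.items()):
                for seq, count in groups:
                    for _ in range(count):
                        fh.write(f">read_{i} sample={sample} amplicon={amp}\n{seq}\n")
                        i += 1


def sample_amplicon_reads(truth: TruthSet, amplicons: list[AmpliconDesign],
                          depth_per_amplicon: int, err: ErrorModel,
                          rng: np.random.Generator | None = None) -> AmpliconReadSet:
    """Emit full-length amplicon reads per sample.

    Per-haplotype read counts are Multinomial(depth, copies/4).  Errors are
    pyrosequencing-style homopolymer indels: with probability
    ``homopolymer_indel_rate`` per mononucleotide run (length >= 3) per read,
    one base is inserted into or deleted from that run.

    Raises ``ValueError`` if a sample's declared haplotype copies are
    inconsistent with its true dosage at the embedded SNP.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + AMPLICON_SEED_OFFSET)
    sample_idx = {s: i for i, s in enumerate(truth.samples)}
    reads: dict[tuple[str, str], list[tuple[str, int]]] = {}
    hap_counts: dict[tuple[str, str], np.ndarray] = {}
    for amp in amplicons:
        if len(amp.consensus) < 420:
            raise ValueError("amplicon shorter than 420 bases")
        hap_seqs = [h.sequence(amp.consensus) for h in amp.haplotypes]
        runs = [_homopolymer_runs(s) for s in hap_seqs]
        for sample, copies in amp.per_sample_copies.items():
            d_true = int(truth.dosage[sample_idx[sample], amp.locus_index])
            d_declared = sum(
                1 for c in copies if amp.haplotypes[c].gbs_allele == 1)
            if d_declared != d_true:
                raise ValueError(
                    f"haplotype copies inconsistent with dosage for {sample} "
                    f"at {amp.amplicon_id}: {d_declared} != {d_true}")
            probs = np.bincount(copies, minlength=len(amp.haplotypes)) / 4.0
            counts = rng.multinomial(depth_per_amplicon, probs)
            groups: list[tuple[str, int]] = []
            for h, c in enumerate(counts):
                if c == 0:
                    continue
                seq, hruns = hap_seqs[h], runs[h]
                p_any = 1.0 - (1.0 - err.homopolymer_indel_rate) ** len(hruns) \
                    if hruns else 0.0
                n_err = rng.binomial(c, p_any) if p_any > 0 else 0
                if c - n_err:
                    groups.append((seq, int(c - n_err)))
                for _ in range(int(n_err)):
                    start, rlen = hruns[int(rng.integers(len(hruns)))]
                    if rng.random() < 0.5:  # insertion
                        mutated = seq[:start] + seq[start] + seq[start:]
                    else:  # deletion
                        mutated = seq[:start] + seq[start + 1:]
                    groups.append((mutated, 1))
            reads[(sample, amp.amplicon_id)] = groups
            hap_counts[(sample, amp.amplicon_id)] = counts
    return AmpliconReadSet(reads=reads, hap_counts=hap_counts)


# --------------------------------------------------------------------------
# calling accuracy law


def het_recovery_probability(depth: int, true_dosage: int,
                             err_rate: float = 0.0) -> float:
    """Probability the diploid caller returns the correct class.

    Exact enumeration over k ~ Binomial(depth, p_eff) A1 reads, where
    p_eff = (d/4)(1 - e) + (1 - d/4) e and ``e`` is the per-read allele-flip
    probability; the one-read rule and the 0.1/0.9 thresholds are applied to
    every (k, depth - k) split.  The correct class is HomA2 / Het / HomA1 for
    dosage 0 / 1-3 / 4.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if true_dosage not in range(5):
        raise ValueError("true_dosage must be in 0..4")
    p = true_dosage / 4.0
    p_eff = p * (1 - err_rate) + (1 - p) * err_rate
    k = np.arange(depth + 1)
    pmf = stats.binom.pmf(k, depth, p_eff)
    calls = gcall.diploid_call(k, depth - k)
    target = {0: gcall.HOM_A2, 4: gcall.HOM_A1}.get(true_dosage, gcall.HET)
    return float(pmf[calls == target].sum())
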