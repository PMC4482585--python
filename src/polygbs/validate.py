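"""Amplicon-based validation of GBS genotype calls.

An independent sequencing platform (e.g. pyrosequencing of ~550-bp
amplicons) re-samples a handful of SNP loci in a few plants.  This module

* labels each amplicon read by exact 64-base identity with one of the two
  GBS alleles (reads covering the tag window but mismatching are
  "imperfect"; reads that cannot be anchored to the consensus are
  "unalignable"),
* reconstructs haplotypes from all variants in the first ``window_length``
  bases of the consensus that reach a 5% within-sample frequency in at
  least one plant, attributing sub-threshold variants to sequencing error,
* derives validation-platform genotype calls with the same ratio rules as
  the GBS caller, and
* classifies GBS-vs-validation concordance per sample-locus, before and
  after genotype-level filtering of the GBS side.

Read anchoring is exact-match seeding on a 20-base consensus word followed
by ungapped extension - adequate because amplicon reads are near-identical
full-length copies of the consensus haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import filters, gcall

SEED_LEN = 20
CATEGORIES = ("concordant_hom", "concordant_het",
              "discordant_gbs_hom_vs_het", "discordant_gbs_het_vs_hom",
              "discordant_ratio", "missing")


# --------------------------------------------------------------------------
# read labelling


def _as_groups(reads):
    if not reads:
        return []
    if isinstance(reads[0], str):
        return [(r, 1) for r in reads]
    return list(reads)


@dataclass
class MatchResult:
    """Per-sample read labels against one GBS locus on one amplicon."""

    counts: pd.DataFrame   # samples x {A1, A2, imperfect, unalignable}
    aligned: dict[str, list[tuple[int, str, int]]]  # sample -> (shift, seq, n)
    tag_start: int

    def fraction_supporting_gbs(self) -> float:
        """Fraction of reads with perfect 64-base identity to an allele."""
        c = self.counts
        total = c.to_numpy().sum()
        return float((c["A1"].sum() + c["A2"].sum()) / total) if total else float("nan")


def match_reads(reads_by_sample: dict, a1: str, a2: str,
                consensus: str) -> MatchResult:
    """Label every amplicon read as A1 / A2 / imperfect / unalignable.

    A read is A1 (A2) when it contains the 64-base allele sequence exactly.
    Otherwise it is anchored to the consensus by a 20-base exact seed within
    the first 100 bases; anchored reads that span the tag window are
    "imperfect", the rest "unalignable".  ``aligned`` retains every
    anchorable read with its consensus offset for haplotype analysis.
    """
    tag_start = consensus.find(a1)
    if tag_start < 0:
        tag_start = consensus.find(a2)
    if tag_start < 0:
        raise ValueError("GBS tag not locatable in amplicon consensus")

    seed_starts = range(0, min(100, len(consensus) - SEED_LEN) + 1, SEED_LEN)
    rows = {}
    aligned: dict[str, list[tuple[int, str, int]]] = {}
    for sample, reads in reads_by_sample.items():
        c = {"A1": 0, "A2": 0, "imperfect": 0, "unalignable": 0}
        keep: list[tuple[int, str, int]] = []
        for seq, count in _as_groups(reads):
            p = seq.find(a1)
            if p >= 0:
                c["A1"] += count
                keep.append((tag_start - p, seq, count))
                continue
            p = seq.find(a2)
            if p >= 0:
                c["A2"] += count
                keep.append((tag_start - p, seq, count))
                continue
            shift = None
            for ss in seed_starts:
                q = seq.find(consensus[ss:ss + SEED_LEN])
                if q >= 0:
                    shift = ss - q
                    break
            if shift is None:
                c["unalignable"] += count
                continue
            covers = (tag_start - shift >= 0
                      and tag_start - shift + 64 <= len(seq))
            if covers:
                c["imperfect"] += count
                keep.append((shift, seq, count))
            else:
                c["unalignable"] += count
        rows[sample] = c
        aligned[sample] = keep
    counts = pd.DataFrame.from_dict(rows, orient="index")[
        ["A1", "A2", "imperfect", "unalignable"]]
    return MatchResult(counts=counts, aligned=aligned, tag_start=tag_start)


# --------------------------------------------------------------------------
# haplotype reconstruction


@dataclass
class Haplotype:
    """A haplotype over the variant positions of one amplicon window."""

    amplicon_id: str
    variants: tuple[tuple[int, str], ...]  # 1-based (position, base), non-consensus only
    window_length: int
    per_sample_counts: dict[str, int]
    gbs_allele_match: str  # "A1" | "A2" | "none"


@dataclass
class HaplotypeTable:
    """Defined haplotypes plus the residual 'other' read pool per sample."""

    amplicon_id: str
    haplotypes: list[Haplotype]
    other_counts: dict[str, int]
    variant_positions: list[int]  # 1-based qualified positions

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_gbs_like(self) -> int:
        return sum(1 for h in self.haplotypes if h.gbs_allele_match != "none")

    def max_gbs_like_per_sample(self) -> dict[str, int]:
        samples = set()
        for h in self.haplotypes:
            samples.update(h.per_sample_counts)
        out = {}
        for s in samples:
            out[s] = sum(1 for h in self.haplotypes
                         if h.gbs_allele_match != "none"
                         and h.per_sample_counts.get(s, 0) > 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, h in enumerate(self.haplotypes):
            row = {"haplotype": f"H{i + 1}",
                   "variants": ",".join(f"{p}{b}" for p, b in h.variants) or ".",
                   "gbs_match": h.gbs_allele_match}
            row.update(h.per_sample_counts)
            rows.append(row)
        return pd.DataFrame(rows)


def define_haplotypes(match: MatchResult, consensus: str, a1: str, a2: str,
                      amplicon_id: str = "", window_length: int = 400,
                      min_freq: float = 0.05,
                      error_radius: int = 2) -> HaplotypeTable:
    """Collapse aligned reads onto haplotypes over qualified variant sites.

    A position qualifies when some non-consensus base reaches ``min_freq``
    within at least one sample (frequency over that sample's window-covering
    reads).  Reads project onto base patterns at qualified positions; a
    pattern is a *defined* haplotype when it reaches ``min_freq`` in some
    sample.  Reads with undefined patterns (sequencing errors) are assigned
    to the nearest defined haplotype within ``error_radius`` mismatches,
    else pooled as "other".
    """
    if window_length > len(consensus):
        raise ValueError("window longer than consensus")
    tag_start = match.tag_start

    # window segments per sample
    segments: dict[str, list[tuple[str, int]]] = {}
    for sample, reads in match.aligned.items():
        segs = []
        for shift, seq, count in reads:
            start = -shift  # read position aligned to consensus 0
            if start < 0 or start + window_length > len(seq):
                continue
            segs.append((seq[start:start + window_length], count))
        segments[sample] = segs

    # qualified variant positions
    window_cons = consensus[:window_length]
    mismatch_freqs: dict[int, float] = {}
    qualified: set[int] = set()
    for sample, segs in segments.items():
        total = sum(c for _, c in segs)
        if total == 0:
            continue
        pos_base: dict[tuple[int, str], int] = {}
        for seg, count in segs:
            for p, (b, cb) in enumerate(zip(seg, window_cons)):
                if b != cb:
                    pos_base[(p, b)] = pos_base.get((p, b), 0) + count
        for (p, b), c in pos_base.items():
            if c / total >= min_freq:
                qualified.add(p)
    positions = sorted(qualified)

    # project reads onto patterns
    pattern_counts: dict[str, dict[tuple, int]] = {}
    for sample, segs in segments.items():
        d: dict[tuple, int] = {}
        for seg, count in segs:
            pat = tuple(seg[p] for p in positions)
            d[pat] = d.get(pat, 0) + count
        pattern_counts[sample] = d

    defined: set[tuple] = set()
    for sample, d in pattern_counts.items():
        total = sum(d.values())
        if total == 0:
            continue
        for pat, c in d.items():
            if c / total >= min_freq:
                defined.add(pat)
    defined_list = sorted(defined)

    # rescue error reads: nearest defined pattern within the radius
    hap_counts: dict[tuple, dict[str, int]] = {p: {} for p in defined_list}
    other: dict[str, int] = {}
    for sample, d in pattern_counts.items():
        other[sample] = 0
        for pat, c in d.items():
            if pat in hap_counts:
                hap_counts[pat][sample] = hap_counts[pat].get(sample, 0) + c
                continue
            best, best_d = None, error_radius + 1
            for cand in defined_list:
                dist = sum(x != y for x, y in zip(pat, cand))
                if dist < best_d:
                    best, best_d = cand, dist
            if best is not None:
                hap_counts[best][sample] = hap_counts[best].get(sample, 0) + c
            else:
                other[sample] += c

    haplotypes = []
    for pat in defined_list:
        b = list(window_cons)
        for p, base in zip(positions, pat):
            b[p] = base
        full = "".join(b) + consensus[window_length:]
        seg64 = full[tag_start:tag_start + 64]
        gbs = "A1" if seg64 == a1 else "A2" if seg64 == a2 else "none"
        variants = tuple((p + 1, base) for p, base in zip(positions, pat)
                         if base != window_cons[p])
        haplotypes.append(Haplotype(
            amplicon_id=amplicon_id, variants=variants,
            window_length=window_length,
            per_sample_counts=hap_counts[pat],
            gbs_allele_match=gbs))
    return HaplotypeTable(amplicon_id=amplicon_id, haplotypes=haplotypes,
                          other_counts=other,
                          variant_positions=[p + 1 for p in positions])


# --------------------------------------------------------------------------
# concordance classification


def validation_call(rc_a1, rc_a2, mode: str = "diploid"):
    """Genotype call from validation-platform counts (same rules as GBS)."""
    fn = gcall.diploid_call if mode == "diploid" else gcall.tetraploid_call
    return fn(rc_a1, rc_a2)


def classify(gbs_code: int, val_code: int, mode: str = "diploid") -> str:
    """Concordance category for one sample-locus.

    Categories: concordant_hom / concordant_het (equal calls), discordant
    sub-classified by the GBS side's class, discordant_ratio (two
    heterozygous dosages that differ - and, by extension, the vanishingly
    rare opposite-homozygote case, which has no printed row of its own),
    and missing (either call missing).
    """
    if mode not in ("diploid", "tetraploid"):
        raise ValueError(f"unknown mode {mode!r}")
    if gbs_code == gcall.MISSING or val_code == gcall.MISSING:
        return "missing"
    if mode == "diploid":
        hom = {gcall.HOM_A1, gcall.HOM_A2}
        gbs_hom, val_hom = gbs_code in hom, val_code in hom
    else:
        gbs_hom, val_hom = gbs_code in (0, 4), val_code in (0, 4)
    if gbs_code == val_code:
        return "concordant_hom" if gbs_hom else "concordant_het"
    if gbs_hom and not val_hom:
        return "discordant_gbs_hom_vs_het"
    if not gbs_hom and val_hom:
        return "discordant_gbs_het_vs_hom"
    return "discordant_ratio"


@dataclass(frozen=True)
class ConcordanceRecord:
    locus: str
    sample: str
    gbs_call: int
    val_call: int
    category: str


def concordance_table(records: list[ConcordanceRecord]) -> dict[str, int]:
    """Category counts over a loci x samples grid (duplicates rejected)."""
    seen = set()
    table = {c: 0 for c in CATEGORIES}
    for r in records:
        key = (r.locus, r.sample)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
        table[r.category] += 1
    return table


@dataclass
class ConcordanceResult:
    """Before/after-filter concordance tables and the transition counts."""

    records_before: list[ConcordanceRecord]
    records_after: list[ConcordanceRecord]
    table_before: dict[str, int]
    table_after: dict[str, int]
    n_concordant_to_missing: int
    n_discordant_to_missing: int

    @staticmethod
    def aggregate(table: dict[str, int]) -> dict[str, int]:
        return {
            "concordant": table["concordant_hom"] + table["concordant_het"],
            "discordant": (table["discordant_gbs_hom_vs_het"]
                           + table["discordant_gbs_het_vs_hom"]
                           + table["discordant_ratio"]),
            "missing": table["missing"],
        }

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, t in (("before", self.table_before),
                        ("after", self.table_after)):
            agg = self.aggregate(t)
            n = sum(t.values())
            rows[name] = {**t, **agg,
                          "total": n,
                          "pct_concordant": 100.0 * agg["concordant"] / n,
                          "pct_discordant": 100.0 * agg["discordant"] / n,
                          "pct_missing": 100.0 * agg["missing"] / n}
        return pd.DataFrame(rows).T


def concordance_analysis(gbs_rc1: pd.DataFrame, gbs_rc2: pd.DataFrame,
                         val_rc1: pd.DataFrame, val_rc2: pd.DataFrame,
                         mode: str = "diploid") -> ConcordanceResult:
    """Full grid comparison of GBS vs validation calls.

    All four matrices are loci x samples with identical labels.  The
    after-filter table re-classifies with genotype-level filters applied to
    the GBS side (calls whose diploid class fails the read-support rules
    become missing, in either mode - the homozygote/heterozygote status the
    rules reference is the same in both).
    """
    for m in (gbs_rc2, val_rc1, val_rc2):
        if not (m.index.equals(gbs_rc1.index) and m.columns.equals(gbs_rc1.columns)):
            raise ValueError("count matrices must share loci and samples")
    call_fn = gcall.diploid_call if mode == "diploid" else gcall.tetraploid_call
    gbs_codes = call_fn(gbs_rc1.to_numpy(), gbs_rc2.to_numpy())
    val_codes = call_fn(val_rc1.to_numpy(), val_rc2.to_numpy())

    gbs_dip = gcall.diploid_call(gbs_rc1.to_numpy(), gbs_rc2.to_numpy())
    filtered_dip = filters.genotype_filter(gbs_dip, gbs_rc1.to_numpy(),
                                           gbs_rc2.to_numpy())
    gbs_after = gbs_codes.copy()
    gbs_after[np.asarray(filtered_dip) == gcall.MISSING] = gcall.MISSING

    loci, samples = gbs_rc1.index, gbs_rc1.columns
    before, after = [], []
    n_cm = n_dm = 0
    for i, locus in enumerate(loci):
        for j, sample in enumerate(samples):
            g, v = int(gbs_codes[i, j]), int(val_codes[i, j])
            cat_b = classify(g, v, mode)
            before.append(ConcordanceRecord(locus, sample, g, v, cat_b))
            ga = int(gbs_after[i, j])
            cat_a = classify(ga, v, mode)
            after.append(ConcordanceRecord(locus, sample, ga, v, cat_a))
            if cat_a == "missing" and cat_b != "missing":
                if cat_b.startswith("concordant"):
                    n_cm += 1
                elif cat_b.startswith("discordant"):
                    n_dm += 1
    return ConcordanceResult(
        records_before=before, records_after=after,
        table_before=concordance_table(before),
        table_after=concordance_table(after),
        n_concordant_to_missing=n_cm, n_discordant_to_missing=n_dm)
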