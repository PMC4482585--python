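"""Reference-free SNP discovery from 64-base GBS tags.

Reads are demultiplexed by exact barcode match, required to carry the ApeKI
cut-site remnant, trimmed to 64 bases and tallied into tags.  Tags supported
by more than ``min_reads`` reads ("good tags") enter a Hamming-distance-1
network; a SNP locus is a *reciprocal tag pair*: two tags that are each
other's sole single-mismatch partner once low-count partners (putative
sequencing-error tags) are set aside.  Tags with several strong partners are
treated as paralogs/repeats and discarded.  No reference genome is used at
any point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simdata import CUT_REMNANT, TAG_LEN

# --------------------------------------------------------------------------
# demultiplexing


@dataclass
class DemuxResult:
    """Good reads per sample (trimmed to 64 bases) plus accounting."""

    sample_reads: dict[str, list[str]]
    good_counts: dict[str, int]
    n_input: int
    n_dropped: int

    def __post_init__(self):
        assert self.n_input == sum(self.good_counts.values()) + self.n_dropped


def read_key(key) -> dict[str, str]:
    """Barcode key as sample_id -> barcode, from TSV path / DataFrame / dict."""
    if isinstance(key, dict):
        mapping = dict(key)
    elif isinstance(key, pd.DataFrame):
        mapping = dict(zip(key["sample_id"], key["barcode"]))
    else:
        df = pd.read_csv(key, sep="\t", dtype=str)
        mapping = dict(zip(df["sample_id"], df["barcode"]))
    barcodes = list(mapping.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in key")
    for a in barcodes:  # prefix-free requirement
        for b in barcodes:
            if a != b and b.startswith(a):
                raise ValueError(f"barcode {a!r} is a prefix of {b!r}")
    return mapping


def _iter_fastq(reads):
    """Yield sequences from a FASTQ path/handle or an iterable of strings."""
    if isinstance(reads, (str, Path)) or hasattr(reads, "read"):
        handle = open(reads) if isinstance(reads, (str, Path)) else reads
        try:
            for i, (_, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                if len(seq) != len(qual):
                    raise ValueError(f"malformed FASTQ record at index {i}")
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ input: {exc}") from exc
        finally:
            if isinstance(reads, (str, Path)):
                handle.close()
    else:
        yield from reads


def demultiplex(reads, key, remnant: str = CUT_REMNANT) -> DemuxResult:
    """Assign reads to samples and trim to 64-base tags.

    A read is *good* iff its prefix matches a barcode exactly, the cut-site
    remnant immediately follows, and the 64 post-barcode bases exist and
    contain no ambiguity (``N``).  Everything else (unknown barcode, missing
    remnant, short read, ambiguous base) is dropped and counted.

    ``reads`` may be a FASTQ path, an open handle, or an iterable of raw
    sequence strings.
    """
    key_map = read_key(key)
    by_len: dict[int, dict[str, str]] = {}
    for sample, bc in key_map.items():
        by_len.setdefault(len(bc), {})[bc] = sample
    lengths = sorted(by_len)

    sample_reads: dict[str, list[str]] = {s: [] for s in key_map}
    n_input = n_dropped = 0
    for seq in _iter_fastq(reads):
        n_input += 1
        sample = None
        for L in lengths:
            s = by_len[L].get(seq[:L])
            if s is not None:
                sample = s
                bc_len = L
                break
        if sample is None:
            n_dropped += 1
            continue
        tag = seq[bc_len:bc_len + TAG_LEN]
        if (len(tag) < TAG_LEN or not tag.startswith(remnant)
                or "N" in tag):
            n_dropped += 1
            continue
        sample_reads[sample].append(tag)
    good_counts = {s: len(r) for s, r in sample_reads.items()}
    return DemuxResult(sample_reads=sample_reads, good_counts=good_counts,
                       n_input=n_input, n_dropped=n_dropped)


# --------------------------------------------------------------------------
# tag tallying


@dataclass
class TagTable:
    """Distinct 64-base tags with total and per-sample read counts."""

    totals: dict[str, int]
    per_sample: dict[str, dict[str, int]]
    samples: list[str]

    @property
    def n_tags(self) -> int:
        return len(self.totals)

    @property
    def n_reads(self) -> int:
        return sum(self.totals.values())

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, (tag, total) in enumerate(sorted(self.totals.items())):
                fh.write(f">tag_{i} count={total}\n{tag}\n")


def tally_tags(sample_reads: dict[str, list[str]]) -> TagTable:
    """Count distinct tags per sample and overall (order-invariant)."""
    totals: Counter[str] = Counter()
    per_sample: dict[str, dict[str, int]] = {}
    for tag in set().union(*map(set, sample_reads.values())) if sample_reads else ():
        per_sample[tag] = {}
    for sample, reads in sample_reads.items():
        counts = Counter(reads)
        totals.update(counts)
        for tag, c in counts.items():
            per_sample[tag][sample] = c
    for tag, by_sample in per_sample.items():
        assert sum(by_sample.values()) == totals[tag]
    return TagTable(totals=dict(totals), per_sample=per_sample,
                    samples=list(sample_reads))


def good_tag_filter(tags: TagTable, min_reads: int = 5) -> TagTable:
    """Retain tags supported by *more than* ``min_reads`` reads (strict)."""
    keep = {t for t, c in tags.totals.items() if c > min_reads}
    return TagTable(totals={t: tags.totals[t] for t in keep},
                    per_sample={t: tags.per_sample[t] for t in keep},
                    samples=tags.samples)


# --------------------------------------------------------------------------
# reciprocal tag pairs


@dataclass(frozen=True)
class SNPLocus:
    """A reciprocal tag pair: two 64-base alleles differing at one position.

    A1 is the higher-count allele (ties broken by lexicographic order)."""

    locus_id: str
    a1: str
    a2: str
    snp_offset: int
    count_a1: int
    count_a2: int
    depths_a1: dict[str, int] = field(default_factory=dict, compare=False)
    depths_a2: dict[str, int] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class NetworkStats:
    n_tags: int
    n_candidate_groups: int  # connected components (size >= 2) of the H1 graph
    n_reciprocal_pairs: int


def _hamming1_edges(tag_list: list[str]) -> list[tuple[int, int]]:
    """All index pairs at Hamming distance exactly 1, by 4-piece indexing.

    A pair differing at one base differs in exactly one of the four 16-base
    quarters, so bucketing on the other three quarters finds each pair once.
    """
    n = len(tag_list)
    if n < 2:
        return []
    q = TAG_LEN // 4
    edges: list[tuple[int, int]] = []
    for piece in range(4):
        lo, hi = piece * q, (piece + 1) * q
        buckets: dict[str, list[int]] = {}
        for i, t in enumerate(tag_list):
            buckets.setdefault(t[:lo] + t[hi:], []).append(i)
        for members in buckets.values():
            if len(members) < 2:
                continue
            for ai in range(len(members)):
                pa = tag_list[members[ai]][lo:hi]
                for bi in range(ai + 1, len(members)):
                    pb = tag_list[members[bi]][lo:hi]
                    # Hamming distance of the held-out quarter must be 1
                    diff = sum(x != y for x, y in zip(pa, pb))
                    if diff == 1:
                        edges.append((members[ai], members[bi]))
    return edges


def find_reciprocal_pairs(tags: TagTable, error_tolerance_rate: float = 0.03):
    """Identify biallelic SNP loci as reciprocal tag pairs.

    Candidate edges join tags at Hamming distance 1.  When assessing a tag's
    partners, any partner whose count is below ``error_tolerance_rate`` times
    the tag's own count is treated as a sequencing-error tag and ignored.  A
    locus is emitted only when each member's sole remaining partner is the
    other.  Returns ``(loci, NetworkStats)``.
    """
    tag_list = sorted(tags.totals)  # deterministic order
    counts = np.array([tags.totals[t] for t in tag_list])
    edges = _hamming1_edges(tag_list)

    neighbors: dict[int, list[int]] = {}
    for i, j in edges:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)

    # candidate groups = connected components with >= 2 tags
    seen: set[int] = set()
    n_groups = 0
    for start in neighbors:
        if start in seen:
            continue
        n_groups += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(w for w in neighbors[v] if w not in seen)

    def strong_partners(i: int) -> list[int]:
        return [j for j in neighbors.get(i, [])
                if counts[j] >= error_tolerance_rate * counts[i]]

    loci: list[SNPLocus] = []
    for i, j in edges:
        if i > j:
            i, j = j, i
        if strong_partners(i) != [j] or strong_partners(j) != [i]:
            continue
        ti, tj = tag_list[i], tag_list[j]
        ci, cj = int(counts[i]), int(counts[j])
        # orientation: higher count is A1; tie -> lexicographically smaller
        if cj > ci or (cj == ci and tj < ti):
            ti, tj, ci, cj = tj, ti, cj, ci
        offset = next(k for k in range(TAG_LEN) if ti[k] != tj[k])
        loci.append(SNPLocus(
            locus_id="", a1=ti, a2=tj, snp_offset=offset,
            count_a1=ci, count_a2=cj,
            depths_a1=dict(tags.per_sample.get(ti, {})),
            depths_a2=dict(tags.per_sample.get(tj, {}))))
    loci.sort(key=lambda l: l.a1)
    loci = [SNPLocus(locus_id=f"TP{i + 1:05d}", a1=l.a1, a2=l.a2,
                     snp_offset=l.snp_offset, count_a1=l.count_a1,
                     count_a2=l.count_a2, depths_a1=l.depths_a1,
                     depths_a2=l.depths_a2)
            for i, l in enumerate(loci)]
    stats = NetworkStats(n_tags=len(tag_list), n_candidate_groups=n_groups,
                         n_reciprocal_pairs=len(loci))
    return loci, stats


def depth_matrices(loci: list[SNPLocus], samples: list[str]):
    """Loci x samples allele-depth matrices (rc1, rc2) as DataFrames."""
    ids = [l.locus_id for l in loci]
    col = {s: k for k, s in enumerate(samples)}
    m1 = np.zeros((len(loci), len(samples)), dtype=int)
    m2 = np.zeros_like(m1)
    for r, l in enumerate(loci):
        for s, c in l.depths_a1.items():
            m1[r, col[s]] = c
        for s, c in l.depths_a2.items():
            m2[r, col[s]] = c
    return (pd.DataFrame(m1, index=ids, columns=samples),
            pd.DataFrame(m2, index=ids, columns=samples))


# --------------------------------------------------------------------------
# read-count cap


@dataclass
class CappedDepths:
    """Allele depths in both capped (pipeline output) and raw form.

    Mirrors genotyping pipelines that store at most ``cap`` reads per allele
    in their final output while the raw tallies remain recoverable."""

    capped_rc1: pd.DataFrame
    capped_rc2: pd.DataFrame
    raw_rc1: pd.DataFrame
    raw_rc2: pd.DataFrame
    cap: int

    def uncap(self):
        """Restore the original (raw) count matrices."""
        return self.raw_rc1, self.raw_rc2


def cap_allele_counts(rc1: pd.DataFrame, rc2: pd.DataFrame,
                      cap: int = 127) -> CappedDepths:
    """Clip every per-sample per-allele count at ``cap`` (default 127)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    return CappedDepths(capped_rc1=rc1.clip(upper=cap),
                        capped_rc2=rc2.clip(upper=cap),
                        raw_rc1=rc1.copy(), raw_rc2=rc2.copy(), cap=cap)
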