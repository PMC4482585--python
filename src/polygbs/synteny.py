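"""Placement of reference-free SNP loci on a syntenic reference genome.

The two 64-base alleles of each locus are searched against a reference
(e.g. a related model species) with BLAST; this module consumes the
precomputed tabular hits (outfmt 6) and applies the placement rules: hits
above the E-value cutoff are ignored, per allele only the top bit score is
retained, a tie for the top score discards the locus, and the two alleles'
retained positions must agree (same chromosome and overlapping intervals,
up to a configurable slack).  Running BLAST itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]

E_CUTOFF = 1e-8


def read_blast_table(hits) -> pd.DataFrame:
    """Parse BLAST outfmt-6 rows; query ids are ``<locus>_<A1|A2>``.

    Accepts a path or a DataFrame already in outfmt-6 column order.
    Malformed rows fail with their line number.
    """
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
        if list(df.columns) != OUTFMT6_COLUMNS:
            df.columns = OUTFMT6_COLUMNS
    else:
        rows = []
        with open(hits) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 12:
                    raise ValueError(
                        f"malformed BLAST tabular row at line {lineno}: "
                        f"expected 12 fields, got {len(parts)}")
                rows.append(parts)
        df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send"):
        df[col] = df[col].astype(int)
    alleles = df["qseqid"].str.rsplit("_", n=1)
    df["locus_id"] = alleles.str[0]
    df["allele"] = alleles.str[1]
    if not df["allele"].isin(["A1", "A2"]).all():
        bad = df.loc[~df["allele"].isin(["A1", "A2"]), "qseqid"].iloc[0]
        raise ValueError(f"query id {bad!r} does not end in _A1/_A2")
    # strand-normalize subject coordinates, keep strand separately
    df["strand"] = pd.Series("+", index=df.index).where(
        df["sstart"] <= df["send"], "-")
    lo = df[["sstart", "send"]].min(axis=1)
    hi = df[["sstart", "send"]].max(axis=1)
    df["sstart"], df["send"] = lo, hi
    return df


@dataclass(frozen=True)
class Assignment:
    locus_id: str
    status: str                 # "single" | "multi" | "discarded" | "unlocated"
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None


def _top_hit(hits: pd.DataFrame):
    """Best hit by bit score; returns (row, tied) with tied=True on a tie."""
    best = hits["bitscore"].max()
    top = hits[hits["bitscore"] == best]
    return top.iloc[0], len(top) > 1


def best_hit_filter(hits, e_cutoff: float = E_CUTOFF,
                    overlap_slack: int = 0) -> list[Assignment]:
    """Assign each locus a unique reference position or a rejection status.

    Per allele the single top bit score is retained; a tie on either allele
    discards the locus.  When both alleles retain a hit, they must fall on
    the same chromosome with subject intervals overlapping (within
    ``overlap_slack`` bases) or the locus is discarded; a locus whose
    alleles produced more than one passing hit overall is located but
    flagged "multi".  Loci with no hit below ``e_cutoff`` are "unlocated".
    """
    df = hits if isinstance(hits, pd.DataFrame) and "locus_id" in hits \
        else read_blast_table(hits)
    out: list[Assignment] = []
    for locus, group in df.groupby("locus_id", sort=True):
        passing = group[group["evalue"] <= e_cutoff]
        if passing.empty:
            out.append(Assignment(locus, "unlocated"))
            continue
        chosen = []
        tied = False
        for _, allele_hits in passing.groupby("allele"):
            row, t = _top_hit(allele_hits)
            tied |= t
            chosen.append(row)
        if tied:
            out.append(Assignment(locus, "discarded"))
            continue
        if len(chosen) == 2:
            a, b = chosen
            same_chrom = a["sseqid"] == b["sseqid"]
            overlap = (a["sstart"] <= b["send"] + overlap_slack
                       and b["sstart"] <= a["send"] + overlap_slack)
            if not (same_chrom and overlap):
                out.append(Assignment(locus, "discarded"))
                continue
        row = chosen[0]
        start = int(min(r["sstart"] for r in chosen))
        end = int(max(r["send"] for r in chosen))
        status = "single" if len(passing) == len(chosen) else "multi"
        out.append(Assignment(locus, status, chromosome=str(row["sseqid"]),
                              start=start, end=end))
    return out


def chromosome_summary(assignments: list[Assignment]) -> dict[str, int]:
    """Counts of single-hit loci per chromosome plus the partition totals.

    The returned dict maps each chromosome to its single-hit locus count and
    adds the keys ``multi``, ``discarded``, ``unlocated`` and ``total``
    (the four statuses partition the loci: per-chromosome counts + multi +
    discarded + unlocated = total).
    """
    summary: dict[str, int] = {}
    multi = discarded = unlocated = 0
    for a in assignments:
        if a.status == "single":
            summary[a.chromosome] = summary.get(a.chromosome, 0) + 1
        elif a.status == "multi":
            multi += 1
        elif a.status == "discarded":
            discarded += 1
        else:
            unlocated += 1
    out = dict(sorted(summary.items()))
    out.update({"multi": multi, "discarded": discarded,
                "unlocated": unlocated, "total": len(assignments)})
    return out
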