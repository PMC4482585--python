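"""Two-level quality filtering of GBS genotype data and summary statistics.

Whole-dataset level: samples with too few good reads are excluded, then loci
are screened on minor allele frequency (MAF >= 0.05) and call rate
(mnC >= 0.5) computed over the retained samples.  Genotype level: individual
calls are set to missing when their read support is inadequate - homozygotes
with fewer than 11 total reads, heterozygotes with fewer than 2 reads of
either allele or a within-genotype minor-allele read frequency (MAF_g) below
0.1.  After genotype-level filtering loci are optionally re-screened on call
rate, yielding the final high-confidence set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gcall

# Default thresholds (population-scale values; scale min_reads down for
# small synthetic runs).
MIN_SAMPLE_READS = 1_000_000
MAF_MIN = 0.05
CALL_RATE_MIN = 0.5
HOM_MIN_TOTAL = 11
HET_MIN_PER_ALLELE = 2
MAF_G_MIN = 0.1


def filter_samples(read_counts, min_reads: int = MIN_SAMPLE_READS):
    """Drop samples with fewer than ``min_reads`` good reads.

    ``read_counts``: mapping or Series sample -> good-read count.
    Returns ``(retained_samples, log)`` where the log records every sample's
    count and fate.  Fails if nothing survives.
    """
    counts = pd.Series(read_counts)
    retained = counts.index[counts >= min_reads].tolist()
    if not retained:
        raise ValueError("no samples pass the read-count threshold")
    log = pd.DataFrame({"reads": counts,
                        "retained": counts >= min_reads})
    return retained, log


def locus_stats(diploid_codes: pd.DataFrame) -> pd.DataFrame:
    """Per-locus MAF and call rate from a loci x samples diploid-call matrix.

    Allele frequency is call-based: HomA1 contributes two A1 alleles, Het one
    of each, over twice the non-missing sample count.  A locus with no
    non-missing call gets MAF = NaN (it then fails any MAF threshold).
    """
    codes = diploid_codes.to_numpy()
    non_missing = (codes != gcall.MISSING).sum(axis=1)
    a1 = np.where(codes == gcall.HOM_A1, 2, 0) + (codes == gcall.HET)
    f = np.divide(a1.sum(axis=1), 2.0 * non_missing,
                  out=np.full(len(codes), np.nan), where=non_missing > 0)
    maf = np.minimum(f, 1.0 - f)
    call_rate = non_missing / codes.shape[1]
    return pd.DataFrame({"maf": maf, "call_rate": call_rate,
                         "n_non_missing": non_missing},
                        index=diploid_codes.index)


def filter_loci(stats: pd.DataFrame, maf_min: float = MAF_MIN,
                call_rate_min: float = CALL_RATE_MIN) -> list[str]:
    """Loci with MAF >= maf_min and call rate >= call_rate_min (inclusive)."""
    keep = (stats["maf"] >= maf_min) & (stats["call_rate"] >= call_rate_min)
    return stats.index[keep.fillna(False)].tolist()


def genotype_filter(diploid_codes, rc1, rc2):
    """Set inadequately supported calls to missing (idempotent).

    Rules (counts are raw, pre one-read-rule): homozygote with total < 11
    reads; heterozygote with < 2 reads of either allele; heterozygote with
    min(rc)/(rc1+rc2) < 0.1.  Never changes a call to a different
    non-missing call.  Accepts scalars or aligned DataFrames/arrays.
    """
    scalar = np.ndim(diploid_codes) == 0
    codes = np.atleast_1d(np.asarray(diploid_codes, dtype=np.int8)).copy()
    a1 = np.atleast_1d(np.asarray(rc1, dtype=float))
    a2 = np.atleast_1d(np.asarray(rc2, dtype=float))
    total = a1 + a2
    hom = (codes == gcall.HOM_A1) | (codes == gcall.HOM_A2)
    het = codes == gcall.HET
    with np.errstate(invalid="ignore", divide="ignore"):
        maf_g = np.where(total > 0, np.minimum(a1, a2) / np.where(total > 0, total, 1), 0.0)
    drop = (hom & (total < HOM_MIN_TOTAL)) | \
           (het & ((a1 < HET_MIN_PER_ALLELE) | (a2 < HET_MIN_PER_ALLELE))) | \
           (het & (maf_g < MAF_G_MIN))
    codes[drop] = gcall.MISSING
    if scalar:
        return int(codes[0])
    if isinstance(diploid_codes, pd.DataFrame):
        return pd.DataFrame(codes, index=diploid_codes.index,
                            columns=diploid_codes.columns)
    return codes


@dataclass
class DatasetSummary:
    """Per-population summary (dataset-wide counts and call frequencies)."""

    n_loci: int
    n_samples: int
    total_reads: int
    reads_per_sample: float
    reads_per_locus: float
    hom_frequency: float   # over non-missing calls
    het_frequency: float
    missing_frequency: float  # over all calls


#: Read-count histogram bin edges for per-call totals (right-inclusive).
HISTOGRAM_BINS = ((1, 10), (11, 200), (201, None))


def summarize(diploid_codes: pd.DataFrame, rc1: pd.DataFrame,
              rc2: pd.DataFrame, populations: dict[str, str]):
    """Per-population DatasetSummary plus the per-call read-count histogram.

    Histogram bins (1-10, 11-200, >200 reads per call) follow the coarse
    groupings used when reporting GBS depth distributions.
    """
    out: dict[str, DatasetSummary] = {}
    hist: dict[str, dict[str, int]] = {}
    pops = pd.Series(populations)
    total = rc1 + rc2
    for pop in sorted(set(pops)):
        cols = [s for s in diploid_codes.columns if pops.get(s) == pop]
        codes = diploid_codes[cols].to_numpy()
        t = total[cols].to_numpy()
        n_calls = codes.size
        non_missing = codes != gcall.MISSING
        n_nm = int(non_missing.sum())
        hom = int(((codes == gcall.HOM_A1) | (codes == gcall.HOM_A2)).sum())
        het = int((codes == gcall.HET).sum())
        reads = int(t.sum())
        out[pop] = DatasetSummary(
            n_loci=codes.shape[0], n_samples=len(cols), total_reads=reads,
            reads_per_sample=reads / max(len(cols), 1),
            reads_per_locus=reads / max(codes.shape[0], 1),
            hom_frequency=hom / n_nm if n_nm else float("nan"),
            het_frequency=het / n_nm if n_nm else float("nan"),
            missing_frequency=1.0 - n_nm / n_calls if n_calls else float("nan"))
        hist[pop] = {
            "1-10": int(((t >= 1) & (t <= 10)).sum()),
            "11-200": int(((t >= 11) & (t <= 200)).sum()),
            ">200": int((t > 200).sum()),
        }
    return out, hist
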