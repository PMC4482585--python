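"""End-to-end orchestration: reads -> tags -> loci -> calls -> filters.

Thin glue over the stage modules, so scripts and tests can run the whole
discovery cascade with one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import filters, gcall, tagnet


@dataclass
class DiscoveryResult:
    """Everything the discovery cascade produces."""

    demux: tagnet.DemuxResult
    tags: tagnet.TagTable
    good_tags: tagnet.TagTable
    loci: list[tagnet.SNPLocus]
    network: tagnet.NetworkStats
    rc1: pd.DataFrame               # loci x retained samples, capped
    rc2: pd.DataFrame
    raw_rc1: pd.DataFrame           # uncapped
    raw_rc2: pd.DataFrame
    retained_samples: list[str]
    diploid_codes: pd.DataFrame     # whole-dataset-filtered loci
    dataset_loci: list[str]
    final_codes: pd.DataFrame       # after genotype-level filter + re-screen
    final_loci: list[str]


def run_discovery(reads, key, min_tag_reads: int = 5,
                  error_tolerance_rate: float = 0.03,
                  min_sample_reads: int = filters.MIN_SAMPLE_READS,
                  maf_min: float = filters.MAF_MIN,
                  call_rate_min: float = filters.CALL_RATE_MIN,
                  cap: int = 127, rescreen_call_rate: bool = True,
                  use_uncapped_counts: bool = True) -> DiscoveryResult:
    """Run demultiplex -> tally -> good tags -> reciprocal pairs ->
    whole-dataset filters -> genotype-level filters.

    ``min_sample_reads`` should be scaled to the experiment (the
    population-scale default of one million reads is far above any
    desk-scale simulation).  ``use_uncapped_counts`` recovers raw counts for
    genotype-level filtering after the 127-read cap, mirroring the recovery
    of counts from the per-sample tag tallies.
    """
    demux = tagnet.demultiplex(reads, key)
    tags = tagnet.tally_tags(demux.sample_reads)
    good = tagnet.good_tag_filter(tags, min_reads=min_tag_reads)
    loci, network = tagnet.find_reciprocal_pairs(
        good, error_tolerance_rate=error_tolerance_rate)

    retained, _ = filters.filter_samples(demux.good_counts,
                                         min_reads=min_sample_reads)
    raw_rc1, raw_rc2 = tagnet.depth_matrices(loci, retained)
    capped = tagnet.cap_allele_counts(raw_rc1, raw_rc2, cap=cap)
    rc1, rc2 = capped.capped_rc1, capped.capped_rc2

    codes = gcall.call_matrix(rc1, rc2, mode="diploid")
    stats = filters.locus_stats(codes)
    dataset_loci = filters.filter_loci(stats, maf_min=maf_min,
                                       call_rate_min=call_rate_min)
    codes_ds = codes.loc[dataset_loci]

    frc1 = (raw_rc1 if use_uncapped_counts else rc1).loc[dataset_loci]
    frc2 = (raw_rc2 if use_uncapped_counts else rc2).loc[dataset_loci]
    filtered = filters.genotype_filter(codes_ds, frc1, frc2)
    if rescreen_call_rate:
        stats2 = filters.locus_stats(filtered)
        final_loci = filters.filter_loci(stats2, maf_min=0.0,
                                         call_rate_min=call_rate_min)
    else:
        final_loci = list(filtered.index)
    return DiscoveryResult(
        demux=demux, tags=tags, good_tags=good, loci=loci, network=network,
        rc1=rc1, rc2=rc2, raw_rc1=raw_rc1, raw_rc2=raw_rc2,
        retained_samples=retained, diploid_codes=codes_ds,
        dataset_loci=dataset_loci, final_codes=filtered.loc[final_loci],
        final_loci=final_loci)


def table2_summary(result: DiscoveryResult) -> dict[str, int]:
    """Run-level counts in the shape of a UNEAK discovery summary."""
    return {
        "total_reads": result.demux.n_input,
        "good_reads": sum(result.demux.good_counts.values()),
        "total_tags": result.tags.n_tags,
        "good_tags": result.good_tags.n_tags,
        "candidate_groups": result.network.n_candidate_groups,
        "reciprocal_tag_pairs": result.network.n_reciprocal_pairs,
        "loci_dataset_filter": len(result.dataset_loci),
        "loci_genotype_filter": len(result.final_loci),
    }
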