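"""Synthetic-data generator: population model, reads, amplicons, accuracy law."""

import numpy as np
import pytest
from scipy import stats

from polygbs import gcall, simdata


# --------------------------------------------------------------------------
# population model


def test_model_validation():
    with pytest.raises(ValueError):
        simdata.PopulationModel(0, 4, np.array([]))
    with pytest.raises(ValueError):
        simdata.PopulationModel(2, 4, np.array([0.5, 1.0]))
    with pytest.raises(ValueError):
        simdata.PopulationModel(2, 4, np.array([0.0, 0.5]))
    with pytest.raises(ValueError):
        simdata.PopulationModel(2, 4, np.array([0.5, 0.5]),
                                shifted_fraction=1.5)


def test_heterozygote_frequency_at_half():
    """p = 0.5: P(dosage in {1,2,3}) = 1 - 2*(1/2)^4 = 0.875 (binomial)."""
    n = 10_000
    model = simdata.PopulationModel(1, n // 2, np.array([0.5]), seed=5)
    truth = simdata.simulate_population(model)
    d = truth.dosage[:, 0]
    het = np.mean((d >= 1) & (d <= 3))
    se = np.sqrt(0.875 * 0.125 / n)
    assert abs(het - 0.875) < 3 * se


def test_dosage_marginal_matches_binomial():
    """Chi-square goodness of fit of dosage counts to Binomial(4, p)."""
    n = 10_000
    for p in (0.2, 0.5, 0.7):
        model = simdata.PopulationModel(1, n // 2, np.array([p]), seed=17)
        truth = simdata.simulate_population(model)
        observed = np.bincount(truth.dosage[:, 0], minlength=5)
        expected = stats.binom.pmf(np.arange(5), 4, p) * n
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.001


def test_no_shift_populations_identical():
    """shift_magnitude = 0: per-locus dosage distributions are exchangeable
    (no per-locus test significant at alpha = 0.01 after Holm control)."""
    model = simdata.PopulationModel.random(30, 400, seed=23)
    truth = simdata.simulate_population(model)
    n = model.n_samples_per_pop
    pvals = []
    for j in range(truth.n_loci):
        a = truth.dosage[:n, j]
        b = truth.dosage[n:, j]
        pvals.append(stats.mannwhitneyu(a, b).pvalue)
    reject = np.sort(pvals) < 0.01 / (np.arange(len(pvals), 0, -1))
    assert not reject.any()


def test_shifted_loci_bookkeeping():
    model = simdata.PopulationModel.random(100, 4, seed=3,
                                           shifted_fraction=0.25,
                                           shift_magnitude=0.2)
    truth = simdata.simulate_population(model)
    assert truth.shifted.sum() == 25
    moved = truth.freqs[0] != truth.freqs[1]
    assert (moved == truth.shifted).all()
    assert np.all((truth.freqs >= 0.01) & (truth.freqs <= 0.99))


def test_determinism_same_seed():
    model = simdata.PopulationModel.random(15, 5, seed=9)
    t1 = simdata.simulate_population(model)
    t2 = simdata.simulate_population(model)
    assert t1.a1 == t2.a1 and t1.a2 == t2.a2
    assert np.array_equal(t1.dosage, t2.dosage)
    r1 = simdata.sample_gbs_reads(t1, simdata.DepthModel(), simdata.ErrorModel())
    r2 = simdata.sample_gbs_reads(t2, simdata.DepthModel(), simdata.ErrorModel())
    assert r1.groups == r2.groups


def test_tag_pair_structure(small_truth):
    for a1, a2, off in zip(small_truth.a1, small_truth.a2,
                           small_truth.snp_offset):
        assert len(a1) == len(a2) == 64
        assert a1.startswith(simdata.CUT_REMNANT)
        diffs = [k for k in range(64) if a1[k] != a2[k]]
        assert diffs == [off]


# --------------------------------------------------------------------------
# GBS reads


def test_read_conservation(noiseless_readset):
    total_truth = int(noiseless_readset.rc1.to_numpy().sum()
                      + noiseless_readset.rc2.to_numpy().sum())
    assert noiseless_readset.n_reads == total_truth
    per_sample = noiseless_readset.reads_per_sample()
    emitted = {}
    for seq, count in noiseless_readset.groups:
        for s, bc in noiseless_readset.barcodes.items():
            if seq.startswith(bc):
                emitted[s] = emitted.get(s, 0) + count
                break
    assert emitted == per_sample.to_dict()


def test_homozygote_reads_carry_single_allele():
    """Dosage 4 and no error: every read at that sample-locus is A1."""
    truth = simdata.simulate_population(
        simdata.PopulationModel(3, 2, np.array([0.99, 0.5, 0.5]), seed=1))
    truth.dosage[:, 0] = 4
    rs = simdata.sample_gbs_reads(
        truth, simdata.DepthModel(mean_depth=20, dropout_prob=0),
        simdata.ErrorModel(substitution_rate=0.0))
    assert (rs.rc2.loc[truth.locus_ids[0]] == 0).all()
    a1 = truth.a1[0]
    for seq, _ in rs.groups:
        assert truth.a2[0] not in seq
    assert any(a1 in seq for seq, _ in rs.groups)


def test_balanced_dosage_symmetric_ratio():
    """Dosage 2: mean A1 read fraction across many sample-loci is 1/2."""
    n_loci = 1000
    truth = simdata.simulate_population(
        simdata.PopulationModel(n_loci, 1, np.full(n_loci, 0.5), seed=2))
    truth.dosage[:] = 2
    rs = simdata.sample_gbs_reads(
        truth, simdata.DepthModel(mean_depth=30, dropout_prob=0),
        simdata.ErrorModel(substitution_rate=0.0))
    rc1 = rs.rc1.to_numpy().ravel().astype(float)
    rc2 = rs.rc2.to_numpy().ravel().astype(float)
    keep = rc1 + rc2 > 0
    ratios = rc1[keep] / (rc1 + rc2)[keep]
    se = ratios.std(ddof=1) / np.sqrt(keep.sum())
    assert abs(ratios.mean() - 0.5) < 3 * se


def test_polymorphic_restriction_site_drops_allele():
    truth = simdata.simulate_population(
        simdata.PopulationModel(2, 4, np.array([0.5, 0.5]), seed=4))
    truth.site_intact[0, 1] = False  # A2 site disrupted at locus 0
    rs = simdata.sample_gbs_reads(
        truth, simdata.DepthModel(mean_depth=25, dropout_prob=0),
        simdata.ErrorModel(substitution_rate=0.0))
    assert (rs.rc2.loc[truth.locus_ids[0]] == 0).all()
    assert rs.rc2.loc[truth.locus_ids[1]].sum() > 0


def test_duplicate_barcodes_rejected(small_truth):
    barcodes = ["ACGTAC"] * small_truth.n_samples
    with pytest.raises(ValueError, match="duplicate"):
        simdata.sample_gbs_reads(small_truth, simdata.DepthModel(),
                                 simdata.ErrorModel(), barcodes=barcodes)


def test_fastq_and_key_roundtrip(tmp_path, noiseless_readset):
    fq = tmp_path / "reads.fastq"
    key = tmp_path / "key.tsv"
    noiseless_readset.write_fastq(fq)
    noiseless_readset.write_key(key)
    n_lines = sum(1 for _ in open(fq))
    assert n_lines == 4 * noiseless_readset.n_reads
    import pandas as pd
    k = pd.read_csv(key, sep="\t")
    assert list(k.columns) == ["sample_id", "population", "barcode"]
    assert len(k) == len(noiseless_readset.barcodes)


# --------------------------------------------------------------------------
# amplicons


def test_amplicon_read_conservation(amplicon_panel):
    samples, designs, reads = amplicon_panel
    for amp in designs:
        for s in samples:
            groups = reads.sample_reads(s, amp.amplicon_id)
            assert sum(c for _, c in groups) == 300
            assert reads.hap_counts[(s, amp.amplicon_id)].sum() == 300


def test_error_free_reads_are_exact_haplotype_copies(amplicon_panel):
    samples, designs, reads = amplicon_panel
    amp = designs[0]
    hap_seqs = {h.sequence(amp.consensus) for h in amp.haplotypes}
    for s in samples:
        for seq, _ in reads.sample_reads(s, amp.amplicon_id):
            assert seq in hap_seqs


def test_homopolymer_errors_produce_rare_private_variants(small_truth):
    samples = small_truth.samples[:8]
    designs = simdata.design_amplicons(small_truth, loci=[0], samples=samples)
    reads = simdata.sample_amplicon_reads(
        small_truth, designs, depth_per_amplicon=400,
        err=simdata.ErrorModel(homopolymer_indel_rate=0.002))
    amp = designs[0]
    hap_seqs = {h.sequence(amp.consensus) for h in amp.haplotypes}
    n_err = n_tot = 0
    for s in samples:
        for seq, c in reads.sample_reads(s, amp.amplicon_id):
            n_tot += c
            if seq not in hap_seqs:
                n_err += c
                assert abs(len(seq) - len(amp.consensus)) == 1  # one indel
    assert 0 < n_err / n_tot < 0.5


def test_haplotype_dosage_inconsistency_rejected(small_truth):
    samples = small_truth.samples[:2]
    designs = simdata.design_amplicons(small_truth, loci=[0], samples=samples)
    amp = designs[0]
    a1_hap = next(i for i, h in enumerate(amp.haplotypes) if h.gbs_allele == 1)
    a2_hap = next(i for i, h in enumerate(amp.haplotypes) if h.gbs_allele == 2)
    # declare a phase whose A1 copy number cannot match the true dosage
    wrong = a2_hap if int(small_truth.dosage[0, 0]) > 0 else a1_hap
    amp.per_sample_copies[samples[0]] = (wrong,) * 4
    with pytest.raises(ValueError, match="inconsistent"):
        simdata.sample_amplicon_reads(small_truth, designs, 50,
                                      simdata.ErrorModel())


def test_amplicon_minimum_length(small_truth):
    with pytest.raises(ValueError):
        simdata.design_amplicons(small_truth, loci=[0],
                                 samples=small_truth.samples[:2], length=300)


# --------------------------------------------------------------------------
# het-recovery law


def test_het_recovery_exact_values():
    assert simdata.het_recovery_probability(4, 2) == pytest.approx(0.375)
    # a single read is always erased by the one-read rule: every depth-1
    # call is missing, so no dosage can be called correctly
    for d in range(5):
        assert simdata.het_recovery_probability(1, d) == 0.0
    # error-free homozygote at depth 2 is always called correctly
    assert simdata.het_recovery_probability(2, 0) == pytest.approx(1.0)
    assert simdata.het_recovery_probability(2, 4) == pytest.approx(1.0)


def test_het_recovery_depth40_near_one():
    assert simdata.het_recovery_probability(40, 2) >= 0.999


def test_het_recovery_monotone_in_depth():
    probs = [simdata.het_recovery_probability(d, 2)
             for d in (2, 4, 8, 16, 32, 64)]
    assert all(b >= a for a, b in zip(probs, probs[1:]))


def test_het_recovery_matches_monte_carlo():
    rng = np.random.default_rng(31)
    n = 10_000
    for depth, dosage in ((8, 2), (16, 1), (12, 4)):
        k = rng.binomial(depth, dosage / 4.0, n)
        calls = gcall.diploid_call(k, depth - k)
        target = {0: gcall.HOM_A2, 4: gcall.HOM_A1}.get(dosage, gcall.HET)
        emp = float(np.mean(calls == target))
        exact = simdata.het_recovery_probability(depth, dosage)
        se = np.sqrt(max(exact * (1 - exact), 1e-9) / n)
        assert abs(emp - exact) < 3 * se + 1e-12


def test_het_recovery_input_validation():
    with pytest.raises(ValueError):
        simdata.het_recovery_probability(0, 2)
    with pytest.raises(ValueError):
        simdata.het_recovery_probability(5, 7)
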