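"""Ground-truth generators: determinism, and each pipeline stage inverting
its generator (adjointness)."""

import io

import numpy as np
import pytest
from scipy import stats

from ypkscreen import evidence as ev
from ypkscreen import lipids, motif, scan, sdl, simulate
from ypkscreen.sdl import SDLGrade
from ypkscreen.simulate import (
    generate_evidence,
    generate_growth_matrices,
    generate_peaklist,
    generate_proteome,
)

ALL_GRADES = list(SDLGrade)


def fasta_bytes(proteins):
    buf = io.StringIO()
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.id, description=p.description) for p in proteins],
        buf,
        "fasta",
    )
    return buf.getvalue().encode()


class TestProteome:
    def test_byte_identical_for_fixed_seed(self):
        a, _ = generate_proteome(n_proteins=6, n_strict=5, n_core=5, seed=123)
        b, _ = generate_proteome(n_proteins=6, n_strict=5, n_core=5, seed=123)
        assert fasta_bytes(a) == fasta_bytes(b)

    def test_different_seeds_differ(self):
        a, _ = generate_proteome(n_proteins=4, seed=1)
        b, _ = generate_proteome(n_proteins=4, seed=2)
        assert fasta_bytes(a) != fasta_bytes(b)

    def test_planted_windows_satisfy_core(self):
        proteins, truth = generate_proteome(n_proteins=8, n_strict=10, n_core=10, seed=9)
        seqs = {p.id: p.sequence for p in proteins}
        for site in truth.planted_sites:
            w = scan.extract_window(seqs[site.protein_id], site.position, motif.DEFAULT_OFFSETS)
            core_ok, plus1, _ = motif.check_constraints(w, "core")
            assert core_ok
            assert plus1 == site.strict_conforming

    def test_core_scan_recovers_all_planted(self, default_matrix):
        """Sensitivity 1.0: every planted core site is found, and the repair
        pass leaves no accidental hits."""
        proteins, truth = generate_proteome(n_proteins=10, n_strict=25, n_core=25, seed=77)
        hits = scan.scan_proteome(proteins, default_matrix, "core", 0.0)
        assert {(h.protein_id, h.position) for h in hits} == {
            (s.protein_id, s.position) for s in truth.planted_sites
        }

    def test_strict_scan_recovers_exactly_strict_sites(self, default_matrix):
        proteins, truth = generate_proteome(n_proteins=10, n_strict=12, n_core=18, seed=78)
        hits = scan.scan_proteome(proteins, default_matrix, "strict", 0.0)
        assert {(h.protein_id, h.position) for h in hits} == {
            (s.protein_id, s.position) for s in truth.planted_sites if s.strict_conforming
        }

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_proteome(n_proteins=0)


class TestEvidenceCohort:
    def test_noiseless_recovery(self):
        cohort = generate_evidence(n_genes=120, flip_rate=0.0, seed=5)
        decisions = ev.classify_all(cohort.hits, cohort.evidence)
        assert all(d.is_candidate == cohort.labels[d.gene_id] for d in decisions)
        for d in decisions:
            if cohort.labels[d.gene_id]:
                assert d.branch == cohort.branches[d.gene_id]

    def test_branch_a_genes_have_at_least_four_sites(self):
        cohort = generate_evidence(n_genes=60, seed=6)
        n_sites = {}
        for h in cohort.hits:
            n_sites[h.protein_id] = n_sites.get(h.protein_id, 0) + 1
        for gene, branch in cohort.branches.items():
            if branch == "a":
                assert n_sites[gene] >= 4

    def test_flip_rate_recovery_matches_binomial_expectation(self):
        """Labels flip iff the gate flag flips, so recovery accuracy is a
        binomial proportion with mean 1 - flip_rate."""
        flip_rate, total, correct = 0.1, 0, 0
        for seed in range(10):
            cohort = generate_evidence(n_genes=100, flip_rate=flip_rate, seed=seed)
            decisions = ev.classify_all(cohort.hits, cohort.evidence)
            correct += sum(d.is_candidate == cohort.labels[d.gene_id] for d in decisions)
            total += len(decisions)
        p = 1 - flip_rate
        se = np.sqrt(p * (1 - p) / total)
        assert abs(correct / total - p) <= 3 * se

    def test_deterministic(self):
        a = generate_evidence(n_genes=30, flip_rate=0.2, seed=11)
        b = generate_evidence(n_genes=30, flip_rate=0.2, seed=11)
        assert a.evidence == b.evidence and a.labels == b.labels

    def test_invalid_flip_rate(self):
        with pytest.raises(ValueError):
            generate_evidence(flip_rate=0.6)


class TestGrowthGenerator:
    def test_round_trip_all_grades_many_seeds(self):
        """Rubric round trip: records built to a target grade are graded
        back to that grade, for all 8 grades across seeds."""
        intents = {f"gene_{g.value}": g for g in ALL_GRADES}
        for seed in range(10):
            records, truth = generate_growth_matrices(intents, seed=seed)
            for rec in records:
                assert sdl.grade_sdl(rec).grade is truth.intended_grades[rec.gene_id]

    def test_p4_construction(self):
        records, _ = generate_growth_matrices({"g": SDLGrade.P4}, seed=0)
        rec = records[0]
        assert rec.growth[("analog_sensitive", "galactose", 1)] == 0
        assert rec.growth[("analog_sensitive", "dextrose", 1)] == rec.control_growth[("analog_sensitive", "dextrose", 1)]

    def test_toxic_construction(self):
        records, _ = generate_growth_matrices({"g": SDLGrade.TOXIC}, seed=0)
        rec = records[0]
        assert (
            rec.control_growth[("wild_type", "galactose", 0)]
            - rec.growth[("wild_type", "galactose", 0)]
            >= 1
        )

    def test_na_records_lack_galactose(self):
        records, _ = generate_growth_matrices({"g": SDLGrade.NA}, seed=0)
        assert not any(c[1] == "galactose" for c in records[0].growth)


class TestPeakGenerator:
    def test_zero_error_recovers_everything_exactly(self):
        peaks, truth = generate_peaklist(error_ppm_sd=0.0, n_noise_peaks=4, seed=3)
        matches, unmatched = lipids.match_peaks(peaks, lipids.default_targets())
        assert len(matches) == len(truth.spiked_species)
        assert all(m.delta_ppm == pytest.approx(0.0, abs=1e-9) for m in matches)
        assert len(unmatched) == 4

    def test_noise_peaks_never_matched(self):
        for seed in range(5):
            peaks, truth = generate_peaklist(error_ppm_sd=1.0, n_noise_peaks=10, seed=seed)
            matches, unmatched = lipids.match_peaks(peaks, lipids.default_targets(), tol_ppm=10)
            spiked = {round(mz, 6) for mz in peaks[: len(truth.spiked_species)]}
            assert all(round(m.observed_mz, 6) in spiked for m in matches)

    def test_recovery_rate_consistent_with_gaussian_tail(self):
        """At 2 ppm error and 10 ppm tolerance the per-peak recovery
        probability is the Gaussian interval mass P(|e| <= 10)."""
        sd, tol, n_rep = 2.0, 10.0, 300
        recovered = total = 0
        for seed in range(n_rep):
            peaks, truth = generate_peaklist(error_ppm_sd=sd, n_noise_peaks=0, seed=seed)
            matches, _ = lipids.match_peaks(peaks, lipids.default_targets(), tol_ppm=tol)
            recovered += len(matches)
            total += len(truth.spiked_species)
        p = stats.norm.cdf(tol / sd) - stats.norm.cdf(-tol / sd)
        se = np.sqrt(p * (1 - p) / total) if p < 1 else 1e-6
        assert abs(recovered / total - p) <= max(3 * se, 1e-4)

    def test_deterministic(self):
        a, _ = generate_peaklist(seed=21)
        b, _ = generate_peaklist(seed=21)
        assert a == b


def test_named_streams_are_independent():
    """Drawing from one generator does not perturb another's output."""
    before, _ = generate_peaklist(seed=42)
    generate_proteome(n_proteins=3, n_strict=2, seed=42)
    generate_evidence(n_genes=10, seed=42)
    after, _ = generate_peaklist(seed=42)
    assert before == after
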