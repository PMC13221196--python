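"""Triage filtering, backbone RMSD profiling, alignment, and diversity."""
import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.spatial.transform import Rotation

from hotforge.ensemble_metrics import (
    column_entropy, confidence_scatter, diversity_report,
    energy_distance_correlation, filter_designs, frequency_matrix, global_align,
    kabsch, normalized_hamming, per_residue_rmsd, residue_correspondence,
)
from hotforge.errors import SuperpositionError
from hotforge.synthetic import HelixDimerSpec, make_helix_dimer


def metrics_df(rows):
    recs = [{"design_id": f"d{i:03d}", "length": 60, "seq": "A" * 60,
             "mean_plddt": p, "ipae": e, "binder_rmsd": 2.0,
             "n_interface_residues": 10, "hotspot_engagement": 3,
             "helicity": 0.8, "mpnn_score": -1.2}
            for i, (p, e) in enumerate(rows)]
    return pd.DataFrame(recs)


class TestFilterDesigns:
    def test_threshold_semantics(self):
        df = metrics_df([(85.0, 10.0), (79.9, 10.0), (85.0, 15.1)])
        kept = filter_designs(df)
        assert list(kept.design_id) == ["d000"]

    def test_boundary_rows_retained_inclusively(self):
        df = metrics_df([(80.0, 15.0)])
        assert len(filter_designs(df)) == 1

    def test_keep_truncates_to_best(self):
        df = metrics_df([(90.0, 5.0 + 0.01 * i) for i in range(150)])
        kept = filter_designs(df, keep=100)
        assert len(kept) == 100
        assert kept.ipae.max() < df.ipae.max()

    def test_output_subset_and_idempotent(self):
        df = metrics_df([(np.random.default_rng(i).uniform(60, 95),
                          np.random.default_rng(i + 99).uniform(5, 25))
                         for i in range(40)])
        once = filter_designs(df)
        twice = filter_designs(once)
        assert set(once.design_id) <= set(df.design_id)
        pd.testing.assert_frame_equal(once, twice)

    def test_ranking_order(self):
        df = metrics_df([(85.0, 9.0), (95.0, 7.0), (90.0, 7.0)])
        kept = filter_designs(df)
        assert list(kept.ipae) == [7.0, 7.0, 9.0]
        assert list(kept.mean_plddt[:2]) == [95.0, 90.0]

    def test_confidence_scatter_is_lossless_projection(self):
        df = metrics_df([(85.0, 9.0), (70.0, 20.0)])
        pts = confidence_scatter(df)
        assert list(pts.columns) == ["design_id", "ipae", "mean_plddt"]
        assert len(pts) == 2
        assert pts.ipae.tolist() == [9.0, 20.0]
        assert len(confidence_scatter(df.iloc[0:0])) == 0


@pytest.fixture(scope="module")
def helix_model():
    return make_helix_dimer(HelixDimerSpec(n_residues=10, separation=8.0, rng_seed=5))


def transformed(model, rotation, translation):
    return model.with_atoms([
        dataclasses.replace(a, position=rotation @ a.position + translation)
        for a in model.atoms])


class TestPerResidueRmsd:
    def test_identical_structures_zero_everywhere(self, helix_model):
        profile = per_residue_rmsd(helix_model, helix_model)
        assert profile.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(profile.per_residue, 0.0, atol=1e-9)

    def test_rigid_transform_invariance(self, helix_model):
        rot = Rotation.from_euler("xyz", [90, 0, 0], degrees=True).as_matrix()
        moved = transformed(helix_model, rot, np.array([5.0, 5.0, 5.0]))
        profile = per_residue_rmsd(moved, helix_model)
        assert profile.global_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_random_rigid_transforms_recover_zero(self, helix_model):
        rng = np.random.default_rng(42)
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(scale=20.0, size=3)
            moved = transformed(helix_model, rot, t)
            profile = per_residue_rmsd(moved, helix_model)
            assert profile.global_rmsd < 1e-6

    def test_single_residue_displacement_recovered(self):
        # large enough that the one displaced residue barely drags the fit
        model = make_helix_dimer(HelixDimerSpec(n_residues=60, separation=8.0, rng_seed=5))
        displaced = model.with_atoms([
            dataclasses.replace(
                a, position=a.position + (np.array([2.0, 0.0, 0.0])
                                          if (a.chain_id, a.res_seq) == ("A", 30) else 0.0))
            for a in model.atoms])
        profile = per_residue_rmsd(displaced, model)
        idx = [i for i, (m, _) in enumerate(profile.residue_pairs) if m == "A:ALA:30"][0]
        assert profile.per_residue[idx] == pytest.approx(2.0, abs=0.2)
        others = np.delete(profile.per_residue, idx)
        assert others.max() < 0.2

    def test_too_few_residues_raises(self, helix_model):
        corr = residue_correspondence(helix_model, helix_model)[:2]
        with pytest.raises(SuperpositionError):
            per_residue_rmsd(helix_model, helix_model, corr)

    def test_global_rmsd_is_rms_over_backbone_atoms(self, helix_model):
        # uniform 1 A displacement of every atom along +x, no rotation:
        # superposition absorbs it -> rmsd 0; anisotropic stretch does not
        stretched = helix_model.with_atoms([
            dataclasses.replace(a, position=a.position * np.array([1.02, 1.0, 1.0]))
            for a in helix_model.atoms])
        profile = per_residue_rmsd(stretched, helix_model)
        # equal atom counts per residue: global rmsd == rms of per-residue rmsds
        manual_global = math.sqrt(float(np.mean(profile.per_residue ** 2)))
        assert profile.global_rmsd == pytest.approx(manual_global, abs=1e-9)


class TestEnergyDistanceCorrelation:
    def _df(self, x, y):
        return pd.DataFrame({"mean_distance_A": x, "sum_e_total": y})

    def test_exact_positive_line(self):
        x = np.array([2.0, 3.0, 4.0, 5.0])
        fit = energy_distance_correlation(self._df(x, 2 * x - 10))
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-10.0)

    def test_exact_inverse_line(self):
        x = np.array([2.0, 3.0, 4.0])
        fit = energy_distance_correlation(self._df(x, -2 * x + 1))
        assert fit.pearson_r == pytest.approx(-1.0)

    def test_constant_energy_flagged_undefined(self):
        fit = energy_distance_correlation(self._df([2.0, 3.0, 4.0], [1.0, 1.0, 1.0]))
        assert not fit.defined
        assert fit.slope is None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            energy_distance_correlation(self._df([1.0, 2.0], [1.0, 2.0]))


BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a, b, open_=11.0, ext=1.0):
    """Exhaustive enumeration over all global alignments (no memoization)."""
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + float(BLOSUM62[a[i], b[j]]), "m")
        if i < len(a):
            rec(i + 1, j, score - ext - (open_ if prev != "gx" else 0.0), "gx")
        if j < len(b):
            rec(i, j + 1, score - ext - (open_ if prev != "gy" else 0.0), "gy")

    rec(0, 0, 0.0, None)
    return best


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.aligned_a == aln.aligned_b == "ACDE"
        assert aln.identity == 1.0

    def test_single_gap_column(self):
        aln = global_align("ACDE", "ACE")
        assert aln.length == 4
        assert aln.aligned_a == "ACDE"
        assert aln.aligned_b.count("-") == 1

    def test_score_symmetry(self):
        for a, b in [("MKV", "MAKV"), ("ACDE", "WW"), ("GGG", "G")]:
            assert global_align(a, b).score == global_align(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")

    def test_matches_exhaustive_enumeration_short(self):
        alphabet = "AC"
        seqs = ["".join(s) for L in (1, 2, 3)
                for s in itertools.product(alphabet, repeat=L)]
        for sa in seqs:
            for sb in seqs:
                assert global_align(sa, sb).score == pytest.approx(
                    brute_force_best_score(sa, sb), abs=1e-9), (sa, sb)

    def test_matches_independent_aligner_on_random_pairs(self):
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(3)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(40):
            sa = "".join(rng.choice(list(alphabet), size=rng.integers(2, 12)))
            sb = "".join(rng.choice(list(alphabet), size=rng.integers(2, 12)))
            assert global_align(sa, sb).score == pytest.approx(
                aligner.score(sa, sb), abs=1e-9), (sa, sb)


class TestDiversity:
    def test_entropy_closed_forms(self):
        assert column_entropy(["A", "A", "A"]) == pytest.approx(0.0)
        assert column_entropy(["A", "C"]) == pytest.approx(1.0)
        assert column_entropy(list("ACDEFGHIKLMNPQRSTVWY")) == pytest.approx(
            math.log2(20), abs=1e-9)

    def test_hamming_closed_forms(self):
        assert normalized_hamming("ACDE", "ACDE") == 0.0
        assert normalized_hamming("AAAA", "CCCC") == 1.0
        with pytest.raises(ValueError):
            normalized_hamming("AA", "AAA")

    def test_identity_matrix_properties(self):
        report = diversity_report(["ACDE", "ACDF", "ACDE", "WCDE"])
        m = report.identity_matrix
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_entropy_bounds_and_conservation(self):
        report = diversity_report(["ACDE", "ACDF", "ACDG"])
        assert (report.entropy_profile >= 0).all()
        assert (report.entropy_profile <= math.log2(20) + 1e-12).all()
        assert np.allclose(report.entropy_profile[:3], 0.0)  # conserved columns
        assert report.entropy_profile[3] == pytest.approx(math.log2(3))

    def test_align_mode_counts_gaps_as_mismatches(self):
        report = diversity_report(["ACDE", "ACE"], mode="align")
        assert report.hamming_distribution[0] == pytest.approx(0.25)

    def test_frequency_matrix_rows_sum_to_one(self):
        fm = frequency_matrix(["ACDE", "ACDF", "ACDE"])
        assert np.allclose(fm.sum(axis=1), 1.0)
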