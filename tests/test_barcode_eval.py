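import numpy as np
import pytest

from barcodekit.barcode_eval import (
    barcoding_gap,
    bcm_threshold,
    best_close_match,
    partition_distances,
    DistancePartition,
)
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.msa_io import Alignment, AlignmentError
from barcodekit.synthetic_data import HierarchicalParams, simulate_hierarchical


def labelled_matrix(species, d):
    labels = tuple(f"R{i}" for i in range(len(species)))
    genera = tuple(s.split()[0] for s in species)
    return DistanceMatrix(labels, tuple(species), genera,
                          np.asarray(d, float), "complete")


@pytest.fixture(scope="module")
def separated():
    p = HierarchicalParams(
        n_genera=5, species_per_genus=4, seqs_per_species=4,
        L=800, d_genus=0.10, d_species=0.08, d_intra=0.005, seed=2,
    )
    aln, truth = simulate_hierarchical(p)
    return aln, truth, distance_matrix(aln)


class TestPartitionDistances:
    def test_two_by_two_counting(self):
        sp = ["Aus bus", "Aus bus", "Aus cus", "Aus cus"]
        d = np.arange(16).reshape(4, 4) / 100.0
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        part = partition_distances(labelled_matrix(sp, d))
        assert len(part.intra) == 2 and len(part.inter) == 4

    def test_single_species_has_no_inter(self):
        sp = ["Aus bus"] * 3
        d = np.full((3, 3), 0.01)
        np.fill_diagonal(d, 0)
        part = partition_distances(labelled_matrix(sp, d))
        assert len(part.inter) == 0 and len(part.intra) == 3

    def test_matches_exhaustive_enumeration(self, separated):
        aln, _, dm = separated
        part = partition_distances(dm)
        expected_intra = [
            dm.d[i, j]
            for i in range(dm.n) for j in range(i + 1, dm.n)
            if dm.species[i] == dm.species[j]
        ]
        assert sorted(part.intra) == pytest.approx(sorted(expected_intra))
        assert len(part.intra) + len(part.inter) + part.n_flagged == \
            dm.n * (dm.n - 1) // 2


class TestBarcodingGap:
    def test_disjoint_distributions(self):
        part = DistancePartition((0.001, 0.002), (0.05, 0.06), 0)
        gap = barcoding_gap(part)
        assert gap.max_intra == 0.002 and gap.min_inter == 0.05
        assert gap.gap == pytest.approx(0.048)
        assert gap.overlap == 0.0

    def test_overlapping_distributions(self):
        gap = barcoding_gap(DistancePartition((0.01,), (0.005,), 0))
        assert gap.gap < 0 and gap.overlap == 1.0

    def test_positive_gap_on_hierarchical_data(self, separated):
        _, _, dm = separated
        gap = barcoding_gap(partition_distances(dm))
        assert gap.gap > 0

    def test_empty_class_is_an_error(self):
        with pytest.raises(AlignmentError, match="intraspecific"):
            barcoding_gap(DistancePartition((), (0.1,), 0))
        with pytest.raises(AlignmentError, match="interspecific"):
            barcoding_gap(DistancePartition((0.1,), (), 0))


class TestBCMThreshold:
    def test_single_value(self):
        part = DistancePartition((0.01,), (0.5,), 0)
        assert bcm_threshold(part, 0.3) == 0.01
        assert bcm_threshold(part, 0.95) == 0.01

    def test_linear_interpolation(self):
        intra = tuple(0.001 * i for i in range(1, 101))
        part = DistancePartition(intra, (0.5,), 0)
        assert bcm_threshold(part, 0.95) == pytest.approx(0.09505, abs=1e-9)

    def test_percentile_one_is_max(self):
        intra = (0.01, 0.07, 0.03)
        part = DistancePartition(intra, (0.5,), 0)
        assert bcm_threshold(part, 1.0) == 0.07


class TestBestCloseMatch:
    def test_perfectly_separated_data_all_correct(self, separated):
        _, _, dm = separated
        part = partition_distances(dm)
        thr = bcm_threshold(part, 1.0)
        rep = best_close_match(dm, thr)
        assert rep.summary["correct"] == pytest.approx(100.0)
        assert rep.summary["fuzzy"] == rep.summary["error"] == 0.0
        assert rep.summary["no_id"] == 0.0

    def test_label_swap_perturbation(self, separated):
        aln, truth, dm = separated
        part = partition_distances(dm)
        thr = bcm_threshold(part, 1.0)
        # relabel one sequence to a different species: that query's nearest
        # neighbours are now "heterospecific" (error), and its 3 former
        # conspecifics see an unchanged nearest set, still all-correct
        species = list(dm.species)
        victim = 0
        donor_species = next(s for s in species if s != species[victim])
        species[victim] = donor_species
        dm2 = DistanceMatrix(dm.labels, tuple(species), dm.genera, dm.d,
                             dm.deletion_policy)
        rep = best_close_match(dm2, thr)
        assert rep.categories[victim] == "error"

        # perturbation oracle: only the victim and former conspecifics whose
        # nearest set touches the victim can change; predict each one
        def nearest_set(q):
            row = dm.d[q].copy()
            row[q] = np.inf
            return set(np.flatnonzero(row <= row.min() + 1e-12))

        expected_wrong = {victim: "error"}
        for q in range(dm.n):
            if q == victim or dm.species[q] != dm.species[victim]:
                continue
            near = nearest_set(q)
            if victim in near:
                expected_wrong[q] = "error" if near == {victim} else "fuzzy"
        for q in range(dm.n):
            if q in expected_wrong:
                assert rep.categories[q] == expected_wrong[q]
            else:
                assert rep.categories[q] == "correct"
        assert rep.summary["correct"] == pytest.approx(
            100.0 * (dm.n - len(expected_wrong)) / dm.n
        )

    def test_all_above_threshold_is_all_no_id(self, separated):
        _, _, dm = separated
        rep = best_close_match(dm, threshold=-1.0)
        assert rep.summary["no_id"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, separated):
        _, _, dm = separated
        for thr in (0.0, 0.001, 0.01, 0.1, np.inf):
            rep = best_close_match(dm, thr)
            assert sum(rep.summary.values()) == pytest.approx(100.0, abs=0.01)

    def test_no_id_monotone_in_threshold(self, separated):
        _, _, dm = separated
        last = 101.0
        for thr in (0.0, 0.005, 0.02, 0.1, np.inf):
            rep = best_close_match(dm, thr)
            assert rep.summary["no_id"] <= last
            last = rep.summary["no_id"]
        assert best_close_match(dm, np.inf).summary["no_id"] == 0.0

    def test_fuzzy_on_exact_tie(self):
        # query 0 ties between a conspecific and a heterospecific reference
        sp = ["Aus bus", "Aus bus", "Aus cus", "Aus cus"]
        d = np.array([
            [0.00, 0.01, 0.01, 0.30],
            [0.01, 0.00, 0.25, 0.30],
            [0.01, 0.25, 0.00, 0.02],
            [0.30, 0.30, 0.02, 0.00],
        ])
        rep = best_close_match(labelled_matrix(sp, d), threshold=0.5)
        assert rep.categories[0] == "fuzzy"

    def test_singleton_species_counted_separately(self):
        sp = ["Aus bus", "Aus bus", "Aus cus"]
        d = np.array([
            [0.00, 0.01, 0.20],
            [0.01, 0.00, 0.20],
            [0.20, 0.20, 0.00],
        ])
        rep = best_close_match(labelled_matrix(sp, d), threshold=0.05)
        assert rep.categories[2] == "no_id"
        assert rep.n_queries == 3 and rep.n_queries_multi == 2
        assert rep.summary_multi["correct"] == pytest.approx(100.0)

    def test_invariant_under_sequence_permutation(self, separated):
        aln, _, dm = separated
        part = partition_distances(dm)
        thr = bcm_threshold(part, 1.0)
        perm = np.arange(dm.n)[::-1]
        dm2 = DistanceMatrix(
            tuple(dm.labels[i] for i in perm),
            tuple(dm.species[i] for i in perm),
            tuple(dm.genera[i] for i in perm),
            dm.d[np.ix_(perm, perm)],
            dm.deletion_policy,
        )
        rep1 = best_close_match(dm, thr)
        rep2 = best_close_match(dm2, thr)
        by_label_1 = dict(zip(dm.labels, rep1.categories))
        by_label_2 = dict(zip(dm2.labels, rep2.categories))
        assert by_label_1 == by_label_2
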