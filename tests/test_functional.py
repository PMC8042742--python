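"""Variant-effect classification, methylation clustering, pseudoheterozygous
assignment, and the functional-copy matrix."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from sklearn.metrics import adjusted_rand_score

from dupincompat.functional import (
    Variant,
    assign_pseudohet_variant,
    build_functional_matrix,
    classify_variant_effect,
    cluster_methylation_profiles,
    impute_profile_matrix,
    methylation_profile_matrix,
    phenotype_from_matrix,
    profile_methylation,
    window_grid,
)
from dupincompat.sim_panel import synthetic_gene_model


@pytest.fixture
def model(rng):
    return synthetic_gene_model("g1", "chr1", rng, tss_bp=1001, n_exons=2)


class TestEffectClassifier:
    def test_intron_snv_is_none(self, model):
        intron_mid = (model.cds_segments[0][1] + model.cds_segments[1][0]) // 2
        v = Variant("chr1", intron_mid, "A", "G")
        assert classify_variant_effect(v, model) == "none"

    def test_outside_span_is_none(self, model):
        assert classify_variant_effect(Variant("chr1", 50, "A", "T"), model) == "none"
        assert classify_variant_effect(Variant("chr9", 1200, "A", "T"), model) == "none"

    def test_one_bp_insertion_in_cds_is_frameshift(self, model):
        pos = model.cds_segments[0][0] + 30
        ref = model.sequence[pos - model.start_bp]
        v = Variant("chr1", pos, ref, ref + "T")
        assert classify_variant_effect(v, model) == "frameshift"

    def test_three_bp_insertion_is_in_frame(self, model):
        pos = model.cds_segments[0][0] + 30
        ref = model.sequence[pos - model.start_bp]
        v = Variant("chr1", pos, ref, ref + "TTT")
        assert classify_variant_effect(v, model) == "none"

    def test_sense_to_stop_snv_is_stop_gained(self, model):
        # scan mid-CDS codons for one a single substitution turns into TAA
        coding = sorted(
            p for s, e in model.cds_segments for p in range(s, e + 1)
        )
        for c in range(3, len(coding) // 3 - 3):
            pos3 = coding[3 * c : 3 * c + 3]
            codon = "".join(model.sequence[p - model.start_bp] for p in pos3)
            diff = [i for i in range(3) if codon[i] != "TAA"[i]]
            if len(diff) == 1:
                i = diff[0]
                v = Variant("chr1", pos3[i], codon[i], "TAA"[i])
                assert classify_variant_effect(v, model) == "stop_gained"
                return
        raise AssertionError("fixture contains no codon one change from TAA")

    def test_start_codon_overlap_is_start_lost(self, model):
        v = Variant("chr1", model.cds_segments[0][0], "A", "G")
        assert classify_variant_effect(v, model) == "start_lost"

    def test_stop_codon_overlap_is_stop_lost(self, model):
        v = Variant("chr1", model.cds_segments[-1][1], "A", "C")
        assert classify_variant_effect(v, model) == "stop_lost"

    def test_splice_edge_is_splice_damage(self, model):
        donor = model.cds_segments[0][1] + 1  # first intron base
        v = Variant("chr1", donor, "G", "A")
        assert classify_variant_effect(v, model) == "splice_damage"

    def test_full_segment_deletion_is_cds_loss(self, rng):
        # middle exon of a 3-exon model: deletion leaves start/stop intact
        model3 = synthetic_gene_model("g3", "chr1", rng, n_exons=3)
        s, e = model3.cds_segments[1]
        ref_start = s - 1
        length = e - ref_start + 1
        ref = model3.sequence[ref_start - model3.start_bp :][:length]
        v = Variant("chr1", ref_start, ref, ref[0])
        assert classify_variant_effect(v, model3) == "cds_loss"


def _codon_walk_oracle(variant, model):
    """Independent oracle: splice the mutated gene sequence by coordinates
    and translate. Classifies stop_gained / frameshift / none only (callers
    restrict variants to CDS-interior, away from start/stop/splice edges)."""
    seq = list(model.sequence)
    offset = model.start_bp
    i = variant.pos - offset
    assert "".join(seq[i : i + len(variant.ref)]) == variant.ref
    mutated = seq[:i] + list(variant.alt) + seq[i + len(variant.ref) :]
    # re-splice: map original CDS coordinates through the indel shift
    shift = len(variant.alt) - len(variant.ref)
    cds = []
    for s, e in sorted(model.cds_segments):
        a, b = s - offset, e - offset
        if shift >= 0:
            a2 = a if a <= i else a + shift
            b2 = b if b < i else b + shift
        else:
            # deletion removes bases (i+1 .. i-shift)
            removed_before = lambda x: min(max(x - i, 0), -shift)
            a2 = a - removed_before(a)
            b2 = b - removed_before(b)
        cds.append("".join(mutated[a2 : b2 + 1]))
    coding = "".join(cds)
    if len(coding) % 3 != len("".join(
        model.sequence[s - offset : e - offset + 1] for s, e in model.cds_segments
    )) % 3:
        return "frameshift"
    prot = str(Seq(coding[: len(coding) // 3 * 3]).translate())
    if "*" in prot[:-1]:
        return "stop_gained"
    return "none"


class TestCodonWalkOracle:
    def test_classifier_agrees_with_translation_oracle(self, rng):
        """1,000 random CDS-interior point variants and small indels are
        classified identically to an independent splice-and-translate
        oracle (stop_gained / frameshift / none)."""
        model = synthetic_gene_model("g", "chr1", rng, n_exons=2, exon_bp=300)
        coding = sorted(
            p for s, e in model.cds_segments for p in range(s, e + 1)
        )
        # interior: clear of start/stop codons and splice edges
        interior = [
            p
            for p in coding[6:-6]
            if all(
                not (e - 2 <= p <= e + 3 or s - 3 <= p <= s + 2)
                for s, e in model.cds_segments
            )
        ]
        n_checked = 0
        for _ in range(1000):
            pos = int(rng.choice(interior))
            ref = model.sequence[pos - model.start_bp]
            kind = rng.integers(3)
            if kind == 0:  # SNV
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = Variant("chr1", pos, ref, alt)
            elif kind == 1:  # insertion of 1-4 bases
                ins = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 5))))
                v = Variant("chr1", pos, ref, ref + ins)
            else:  # deletion of 1-4 bases, kept inside the same exon
                ndel = int(rng.integers(1, 5))
                if any(pos < s <= pos + ndel or pos < e + 1 <= pos + ndel
                       for s, e in model.cds_segments):
                    continue
                ref_del = model.sequence[
                    pos - model.start_bp : pos - model.start_bp + ndel + 1
                ]
                v = Variant("chr1", pos, ref_del, ref_del[0])
            got = classify_variant_effect(v, model)
            want = _codon_walk_oracle(v, model)
            assert got == want, (v, got, want)
            n_checked += 1
        assert n_checked > 600


class TestMethylationProfile:
    def _report(self, model, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "context", "count_methylated", "count_total"],
        )

    def test_fully_methylated_window_is_100(self, model):
        pos = model.tss_bp - 450
        rep = self._report(model, [("chr1", pos, "+", "CG", 8, 8)])
        prof = profile_methylation(rep, model)
        assert prof.loc[(0, "CG")] == 100.0

    def test_mixed_counts_percentage(self, model):
        pos = model.tss_bp - 450
        rep = self._report(model, [("chr1", pos, "+", "CHG", 3, 10)])
        prof = profile_methylation(rep, model)
        assert prof.loc[(0, "CHG")] == pytest.approx(30.0)

    def test_uncovered_window_missing_then_imputed(self, model):
        pos = model.tss_bp - 450
        rep = self._report(model, [("chr1", pos, "+", "CG", 5, 10)])
        prof = profile_methylation(rep, model)
        assert np.isnan(prof.loc[(1, "CG")])
        mat = impute_profile_matrix(pd.DataFrame({"acc": prof}).T)
        assert mat.loc["acc", (1, "CG")] == pytest.approx(50.0)

    def test_window_count_covers_full_span(self, model):
        span = abs(model.tes_bp - model.tss_bp) + 1 + 800
        assert window_grid(model) == int(np.ceil(span / 100))


def _greedy_ward_oracle(x):
    """Brute-force Ward agglomeration: at each step merge the pair of
    clusters with the smallest increase in within-cluster sum of squares."""
    clusters = [{i} for i in range(len(x))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = np.array(sorted(clusters[i]))
                b = np.array(sorted(clusters[j]))
                ma, mb = x[a].mean(axis=0), x[b].mean(axis=0)
                cost = (
                    len(a) * len(b) / (len(a) + len(b))
                    * float(((ma - mb) ** 2).sum())
                )
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        _, i, j = best
        merges.append(frozenset(clusters[i] | clusters[j]))
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [clusters[i] | clusters[j]]
    return merges


class TestClustering:
    def _two_class_profiles(self, rng, n_per=20, mean_high=80.0, mean_low=5.0, sd=5.0):
        cols = pd.MultiIndex.from_product(
            [range(10), ["CG", "CHG", "CHH"]], names=["window", "context"]
        )
        rows = {}
        truth = {}
        for i in range(n_per):
            rows[f"hi{i}"] = np.clip(rng.normal(mean_high, sd, len(cols)), 0, 100)
            truth[f"hi{i}"] = 1
            rows[f"lo{i}"] = np.clip(rng.normal(mean_low, sd, len(cols)), 0, 100)
            truth[f"lo{i}"] = 0
        return pd.DataFrame(rows, index=cols).T, pd.Series(truth)

    def test_separated_classes_recovered_exactly(self, rng):
        profiles, truth = self._two_class_profiles(rng)
        labels = cluster_methylation_profiles(profiles)
        assert adjusted_rand_score(truth, labels == "hypermethylated") == 1.0
        # the high-mean class is the one labelled hypermethylated
        assert (labels[truth == 1] == "hypermethylated").all()

    def test_two_distinct_profiles_split(self, rng):
        profiles, _ = self._two_class_profiles(rng, n_per=1)
        labels = cluster_methylation_profiles(profiles)
        assert set(labels) == {"hypermethylated", "unmethylated"}

    def test_permutation_invariance(self, rng):
        profiles, _ = self._two_class_profiles(rng, n_per=10)
        labels = cluster_methylation_profiles(profiles)
        perm = profiles.sample(frac=1.0, random_state=1)
        labels_perm = cluster_methylation_profiles(perm)
        assert (labels_perm.loc[labels.index] == labels).all()

    def test_identical_profiles_warn_single_group(self, rng):
        cols = pd.MultiIndex.from_product(
            [range(4), ["CG", "CHG", "CHH"]], names=["window", "context"]
        )
        profiles = pd.DataFrame(
            [np.full(len(cols), 10.0)] * 3, index=list("abc"), columns=cols
        )
        with pytest.warns(UserWarning):
            labels = cluster_methylation_profiles(profiles)
        assert (labels == "unmethylated").all()

    def test_merge_sequence_matches_greedy_ward_oracle(self, rng):
        """For n <= 10 the scipy Ward tree reproduces the brute-force greedy
        minimum-variance merge sequence."""
        from scipy.cluster.hierarchy import linkage

        for n in (4, 6, 8, 10):
            x = rng.normal(size=(n, 5))
            z = linkage(x, method="ward")
            # reconstruct scipy's merge sets
            members = {i: frozenset([i]) for i in range(n)}
            scipy_merges = []
            for k, (i, j, _, _) in enumerate(z):
                merged = members[int(i)] | members[int(j)]
                members[n + k] = merged
                scipy_merges.append(merged)
            assert scipy_merges == _greedy_ward_oracle(x)

    def test_separate_cohorts_clustered_independently(self, rng):
        profiles, truth = self._two_class_profiles(rng, n_per=6)
        # alternate (hypermethylated, unmethylated) pairs between cohorts so
        # each cohort contains both classes
        cohorts = pd.Series(
            ["c1" if i % 4 < 2 else "c2" for i in range(len(profiles))],
            index=profiles.index,
        )
        labels = cluster_methylation_profiles(profiles, cohorts=cohorts)
        assert adjusted_rand_score(truth, labels == "hypermethylated") == 1.0


class TestPseudohetAssignment:
    METH = {"copy1": "unmethylated", "copy2": "hypermethylated"}

    def test_dna_only_goes_to_silenced_copy(self):
        assert assign_pseudohet_variant(True, False, self.METH) == "copy2"

    def test_dna_and_rna_goes_to_expressed_copy(self):
        assert assign_pseudohet_variant(True, True, self.METH) == "copy1"

    def test_no_expression_contrast_unassigned(self):
        both = {"copy1": "unmethylated", "copy2": "unmethylated"}
        assert assign_pseudohet_variant(True, True, both) is None
        silenced = {"copy1": "hypermethylated", "copy2": "hypermethylated"}
        assert assign_pseudohet_variant(True, False, silenced) is None

    def test_absent_in_dna_is_an_error(self):
        with pytest.raises(ValueError):
            assign_pseudohet_variant(False, True, self.METH)


class TestFunctionalMatrix:
    def _frames(self, **cells):
        acc = ["a1"]
        copies = ["copy1", "copy2"]
        lof = pd.DataFrame(False, index=acc, columns=copies)
        meth = pd.DataFrame("unmethylated", index=acc, columns=copies)
        present = pd.DataFrame(True, index=acc, columns=copies)
        return lof, meth, present

    def test_deleted_copy_with_functional_paralog(self):
        lof, meth, present = self._frames()
        present.loc["a1", "copy1"] = False
        matrix, _ = build_functional_matrix(lof, meth, present)
        assert matrix.loc["a1", "copy1"] == "absent"
        assert matrix.loc["a1", "copy2"] == "functional"
        assert phenotype_from_matrix(matrix)["a1"] == 1

    def test_lof_plus_silenced_gives_zero_functional(self):
        lof, meth, present = self._frames()
        lof.loc["a1", "copy1"] = True
        meth.loc["a1", "copy2"] = "hypermethylated"
        matrix, _ = build_functional_matrix(lof, meth, present)
        assert matrix.loc["a1", "copy1"] == "lof"
        assert matrix.loc["a1", "copy2"] == "silenced"
        assert phenotype_from_matrix(matrix)["a1"] == 0

    def test_no_evidence_defaults_to_functional(self):
        lof, _, _ = self._frames()
        matrix, prov = build_functional_matrix(lof)
        assert (matrix == "functional").all().all()

    def test_conflict_absent_but_expressed_is_unknown(self):
        lof, meth, present = self._frames()
        present.loc["a1", "copy1"] = False
        rna = pd.DataFrame(True, index=["a1"], columns=["copy1", "copy2"])
        matrix, prov = build_functional_matrix(lof, meth, present, rna)
        assert matrix.loc["a1", "copy1"] == "unknown"
        assert "conflict" in prov.loc["a1", "copy1"]

    def test_adding_lof_never_restores_function(self, rng):
        # monotonicity: flipping any lof cell on can only degrade the state
        acc = [f"a{i}" for i in range(10)]
        copies = ["c1", "c2"]
        lof = pd.DataFrame(
            rng.random((10, 2)) < 0.3, index=acc, columns=copies
        )
        meth = pd.DataFrame(
            np.where(rng.random((10, 2)) < 0.3, "hypermethylated", "unmethylated"),
            index=acc,
            columns=copies,
        )
        base, _ = build_functional_matrix(lof, meth)
        more = lof.copy()
        more.iloc[0, 0] = True
        after, _ = build_functional_matrix(more, meth)
        was_func = base == "functional"
        assert not ((after == "functional") & ~was_func).any().any()

    def test_phenotype_modes(self):
        matrix = pd.DataFrame(
            {
                "ref": ["silenced", "lof", "functional"],
                "paralog": ["functional", "lof", "functional"],
                "modifier": ["absent", "functional", "absent"],
            },
            index=["a", "b", "c"],
        )
        any_copy = phenotype_from_matrix(matrix, "any_copy")
        assert any_copy.tolist() == [1, 1, 1]
        ref_only = phenotype_from_matrix(matrix, "reference_copy", "ref")
        assert ref_only.tolist() == [0, 0, 1]
        all_bad = pd.DataFrame({"c1": ["lof"], "c2": ["silenced"]}, index=["x"])
        assert phenotype_from_matrix(all_bad).tolist() == [0]
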