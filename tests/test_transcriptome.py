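"""Gene-metabolism correlation, empirical-null calibration, module-wise runs."""

import numpy as np
import pytest
from scipy import stats

import metacov as mc


def _profile(values, names=None, group="g"):
    values = np.asarray(values, dtype=float)
    names = names or tuple(f"r{i}" for i in range(values.size))
    return mc.MetabolismProfile(tuple(names), values, group)


def _genes(rows, names=None, consistency=None, symbols=None):
    rows = np.asarray(rows, dtype=float)
    names = names or [f"r{i}" for i in range(rows.shape[1])]
    return mc.GeneExpressionTable(
        gene_symbols=symbols or [f"G{i}" for i in range(rows.shape[0])],
        roi_names=list(names),
        expression=rows,
        consistency=(
            np.asarray(consistency)
            if consistency is not None
            else np.full(rows.shape[0], 0.9)
        ),
    )


class TestMeanProfile:
    def test_single_subject_identity(self, atlas):
        rng = np.random.default_rng(0)
        row = 1.5 + 0.1 * rng.standard_normal(atlas.n_rois)
        table = mc.SuvrTable(
            subject_ids=["only"],
            roi_names=list(atlas.names),
            values=row[np.newaxis, :],
            group=np.array(["g"], dtype=object),
        )
        profile = mc.mean_metabolism_profile(table)
        np.testing.assert_allclose(profile.mean_suvr, row)

    def test_mirror_pair_gives_constant(self, atlas):
        rng = np.random.default_rng(1)
        r = 1.5 + 0.1 * rng.standard_normal(atlas.n_rois)
        c = 1.5
        table = mc.SuvrTable(
            subject_ids=["a", "b"],
            roi_names=list(atlas.names),
            values=np.vstack([r, -r + 2 * c]),
            group=np.array(["g", "g"], dtype=object),
        )
        profile = mc.mean_metabolism_profile(table)
        np.testing.assert_allclose(profile.mean_suvr, c)

    def test_hand_summed_means(self, atlas):
        values = np.array([[1.0, 2.0, 4.0], [2.0, 2.0, 5.0], [3.0, 5.0, 6.0]])
        full = np.tile(values, (1, 24))
        table = mc.SuvrTable(
            subject_ids=["a", "b", "c"],
            roi_names=list(atlas.names),
            values=full,
            group=np.array(["g"] * 3, dtype=object),
        )
        profile = mc.mean_metabolism_profile(table)
        np.testing.assert_allclose(profile.mean_suvr[:3], [2.0, 3.0, 5.0])

    def test_subset_restriction(self, atlas, small_suvr_table):
        cortical = atlas.cortical_names
        profile = mc.mean_metabolism_profile(small_suvr_table, rois=cortical)
        assert profile.roi_names == tuple(cortical)
        with pytest.raises(mc.ValidationError):
            mc.mean_metabolism_profile(small_suvr_table, rois=[])


class TestGeneCorrelation:
    def test_identical_profile_r_one(self):
        p = _profile([1.1, 1.3, 1.2, 1.5, 1.4])
        res = mc.gene_metabolism_correlation(_genes([p.mean_suvr]), p)
        assert res[0].r == pytest.approx(1.0)

    def test_reflected_profile_r_minus_one(self):
        p = _profile([1.1, 1.3, 1.2, 1.5, 1.4])
        res = mc.gene_metabolism_correlation(_genes([3.0 - p.mean_suvr]), p)
        assert res[0].r == pytest.approx(-1.0)

    def test_hand_covariance_oracle(self):
        # gene (1..5) vs profile (1,2,3,4,6): r = 12 / sqrt(10 * 14.8)
        p = _profile([1, 2, 3, 4, 6])
        res = mc.gene_metabolism_correlation(_genes([[1, 2, 3, 4, 5]]), p)
        assert res[0].r == pytest.approx(12.0 / np.sqrt(148.0), abs=1e-12)

    def test_r_and_p_match_scipy_pearsonr(self):
        rng = np.random.default_rng(2)
        p = _profile(1.5 + 0.1 * rng.standard_normal(20))
        rows = rng.standard_normal((5, 20))
        results = mc.gene_metabolism_correlation(_genes(rows), p)
        for row, res in zip(rows, results):
            expected = stats.pearsonr(row, p.mean_suvr)
            assert res.r == pytest.approx(expected.statistic, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(expected.pvalue, rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        p = _profile(1.5 + 0.1 * rng.standard_normal(10))
        row = rng.standard_normal(10)
        base = mc.gene_metabolism_correlation(_genes([row]), p)[0].r
        scaled = mc.gene_metabolism_correlation(_genes([2.5 * row + 7.0]), p)[0].r
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_flat_gene_flagged_not_dropped(self):
        p = _profile([1, 2, 3, 4, 5])
        results = mc.gene_metabolism_correlation(
            _genes([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]]), p
        )
        assert results[0].degenerate and np.isnan(results[0].r)
        assert not results[1].degenerate

    def test_too_few_shared_rois(self):
        p = _profile([1.0, 2.0], names=("a", "b"))
        with pytest.raises(mc.SampleSizeError):
            mc.gene_metabolism_correlation(
                _genes([[1.0, 2.0]], names=["a", "b"]), p
            )

    def test_sortable_by_r_descending(self):
        rng = np.random.default_rng(4)
        p = _profile(1.5 + 0.1 * rng.standard_normal(12))
        results = mc.gene_metabolism_correlation(
            _genes(rng.standard_normal((6, 12))), p
        )
        ordered = sorted(results, key=lambda res: res.r, reverse=True)
        assert ordered[0].r >= ordered[-1].r


def _orthonormal_pair(n, seed=0):
    """Two centred unit vectors, the second orthogonal to the first."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b = rng.standard_normal(n)
    b -= b.mean()
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


class TestTranscriptomeNull:
    def test_constructed_r_values(self):
        """Genes built at exact r in {-0.5, 0, 0.5}: mean 0, sd 0.5 (n-1)."""
        n = 10
        a, b = _orthonormal_pair(n, seed=5)
        profile_values = 1.5 + 0.1 * a
        genes = _genes(
            [
                -0.5 * a + np.sqrt(0.75) * b,
                b,
                0.5 * a + np.sqrt(0.75) * b,
            ],
            names=[f"r{i}" for i in range(n)],
        )
        p = _profile(profile_values)
        null = mc.transcriptome_null(genes, p)
        np.testing.assert_allclose(
            np.sort(null.r_values), [-0.5, 0.0, 0.5], atol=1e-10
        )
        assert null.mean == pytest.approx(0.0, abs=1e-10)
        assert null.sd == pytest.approx(0.5, abs=1e-10)

    def test_orthogonal_fixture_mean_zero(self):
        a, b = _orthonormal_pair(16, seed=6)
        genes = _genes([b, 2 * b, -b + 1.0])
        null = mc.transcriptome_null(genes, _profile(1.5 + 0.1 * a))
        assert null.mean == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_background_mean(self):
        rng = np.random.default_rng(7)
        genes = _genes(rng.standard_normal((5000, 68)))
        null = mc.transcriptome_null(genes, _profile(1.5 + 0.1 * rng.standard_normal(68)))
        assert abs(null.mean) < 0.02
        assert null.n_genes == 5000

    def test_degenerate_genes_excluded_with_count(self):
        rng = np.random.default_rng(8)
        rows = rng.standard_normal((4, 10))
        rows[2] = 3.0
        null = mc.transcriptome_null(
            _genes(rows), _profile(1.5 + 0.1 * rng.standard_normal(10))
        )
        assert null.n_degenerate == 1
        assert null.n_genes == 3


class TestNullCalibration:
    @pytest.mark.parametrize(
        "z,expected",
        [(2.228, 0.0130), (-2.208, 0.0136), (-2.353, 0.0093), (0.0, 0.5)],
    )
    def test_normal_tail_worked_examples(self, z, expected):
        assert mc.p_e_from_z(z) == pytest.approx(expected, abs=1e-4)

    def test_calibrate_fills_z_and_pe(self):
        null = mc.NullDistribution(
            r_values=np.array([-0.2, 0.0, 0.2]), mean=0.0, sd=0.3, n_genes=3
        )
        res = mc.GeneCorrelationResult("APOE", r=-0.746, p_two_tailed=1e-5, n_rois=68)
        out = mc.calibrate_against_null(res, null)
        assert out.z == pytest.approx(-0.746 / 0.3)
        assert out.p_e == pytest.approx(stats.norm.sf(0.746 / 0.3), abs=1e-12)
        assert np.sign(out.z) == np.sign(res.r - null.mean)

    def test_self_calibration_standardises(self):
        """z of every null gene against its own null: mean 0, sd 1."""
        rng = np.random.default_rng(9)
        genes = _genes(rng.standard_normal((500, 30)))
        p = _profile(1.5 + 0.1 * rng.standard_normal(30))
        null = mc.transcriptome_null(genes, p)
        z = (null.r_values - null.mean) / null.sd
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10

    def test_pe_decreasing_in_abs_z_and_sign_symmetric(self):
        zs = np.linspace(0.0, 4.0, 30)
        pes = [mc.p_e_from_z(z) for z in zs]
        assert all(b < a for a, b in zip(pes, pes[1:]))
        for z in (0.5, 1.7, 2.9):
            assert mc.p_e_from_z(z) == mc.p_e_from_z(-z)

    def test_planted_genes_exceed_two_sigma(self):
        """|r_true| = 0.7 among 5000 noise genes lands beyond |z| = 2."""
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profile = mc.MetabolismProfile(
                tuple(f"r{i}" for i in range(68)),
                1.5 + 0.15 * rng.standard_normal(68),
            )
            config = mc.SyntheticTranscriptomeConfig(
                n_background_genes=5000,
                planted=tuple((f"P{i}", 0.7 if i % 2 else -0.7) for i in range(5)),
                seed=seed,
            )
            genes = mc.simulate_transcriptome(config, profile)
            null = mc.transcriptome_null(genes, profile)
            for res in mc.gene_metabolism_correlation(genes, profile)[:5]:
                out = mc.calibrate_against_null(res, null)
                total += 1
                hits += abs(out.z) > 2.0
        assert hits / total >= 0.9


class TestModuleWise:
    def _setup(self, atlas):
        rng = np.random.default_rng(10)
        profile = mc.MetabolismProfile(
            atlas.names, 1.5 + 0.15 * rng.standard_normal(72)
        )
        cortical = list(atlas.cortical_names)
        idx = [atlas.names.index(r) for r in cortical]
        genes = mc.GeneExpressionTable(
            gene_symbols=["G0", "G1"],
            roi_names=cortical,
            expression=np.vstack(
                [profile.mean_suvr[idx], rng.standard_normal(68)]
            ),
            consistency=np.array([0.9, 0.9]),
        )
        return profile, genes

    def test_subcortical_only_module_undefined(self, atlas):
        profile, genes = self._setup(atlas)
        labels = np.ones(72, dtype=int)
        labels[:4] = 2  # the four subcortical nodes
        modules = mc.module_wise_correlation(
            genes, profile, mc.Partition(labels), atlas
        )
        undefined = [m for m in modules if not m.defined]
        defined = [m for m in modules if m.defined]
        assert len(undefined) == 1 and len(undefined[0].roi_names) == 0
        assert len(defined) == 1 and len(defined[0].roi_names) == 68

    def test_single_module_equals_global_cortical(self, atlas):
        profile, genes = self._setup(atlas)
        modules = mc.module_wise_correlation(
            genes, profile, mc.Partition(np.ones(72, dtype=int)), atlas
        )
        assert len(modules) == 1
        direct = mc.gene_metabolism_correlation(
            genes, profile.restrict(genes.roi_names)
        )
        for a, b in zip(modules[0].results, direct):
            assert a.r == pytest.approx(b.r, abs=1e-12)
            assert a.n_rois == b.n_rois == 68

    def test_planted_module_signal(self, atlas):
        """Gene tracking the profile inside module A only: r(A) > r(B)."""
        rng = np.random.default_rng(11)
        labels = np.ones(72, dtype=int)
        labels[40:] = 2
        profile = mc.MetabolismProfile(
            atlas.names, 1.5 + 0.15 * rng.standard_normal(72)
        )
        cortical = list(atlas.cortical_names)
        idx = [atlas.names.index(r) for r in cortical]
        in_a = labels[idx] == 1
        expr = rng.standard_normal(68)
        expr[in_a] = profile.mean_suvr[idx][in_a] + 0.01 * rng.standard_normal(
            int(in_a.sum())
        )
        genes = mc.GeneExpressionTable(
            gene_symbols=["G0"], roi_names=cortical,
            expression=expr[np.newaxis, :], consistency=np.array([0.9]),
        )
        modules = mc.module_wise_correlation(
            genes, profile, mc.Partition(labels), atlas
        )
        by_label = {m.module: m for m in modules}
        r_a = by_label[1].results[0].r
        r_b = by_label[2].results[0].r
        assert r_a > r_b
        # each matches a direct evaluation on the subset
        for label in (1, 2):
            rois = list(by_label[label].roi_names)
            sub_idx = [cortical.index(r) for r in rois]
            expected = stats.pearsonr(
                expr[sub_idx], profile.restrict(rois).mean_suvr
            ).statistic
            assert by_label[label].results[0].r == pytest.approx(expected, abs=1e-12)


def test_significance_stars_cutoffs():
    assert mc.significance_stars(0.04) == "*"
    assert mc.significance_stars(0.009) == "**"
    assert mc.significance_stars(0.0009) == "***"
    assert mc.significance_stars(0.00005) == "****"
    assert mc.significance_stars(0.2) == ""
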