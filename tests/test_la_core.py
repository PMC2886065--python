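import itertools

import numpy as np
import pytest

from lascout.data_model import ExpressionDataset
from lascout.la_core import la_score, lead_set_report, scout_z, search_pairs
from lascout.preprocess import transform_dataset


def naive_la(x, y, z, total_n=False):
    """Brute-force oracle: explicit loop over complete triples."""
    s, n = 0.0, 0
    for xi, yi, zi in zip(x, y, z):
        if not (np.isnan(xi) or np.isnan(yi) or np.isnan(zi)):
            s += xi * yi * zi
            n += 1
    return s / (len(x) if total_n else n), n


class TestLaScore:
    def test_hand_arithmetic(self):
        r = la_score([1.0, -1.0, 1.0], [1.0, -1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.la_score == pytest.approx(1.0) and r.n_used == 3

    def test_zero_mediator_annihilates(self, rng):
        x, y = rng.standard_normal((2, 10))
        assert la_score(x, y, np.zeros(10)).la_score == 0.0

    def test_matches_naive_with_missing(self, rng):
        x, y, z = rng.standard_normal((3, 40))
        for v in (x, y, z):
            v[rng.random(40) < 0.15] = np.nan
        r = la_score(x, y, z)
        expect, n = naive_la(x, y, z)
        assert r.la_score == pytest.approx(expect, abs=1e-12) and r.n_used == n

    def test_total_n_denominator(self, rng):
        x, y, z = rng.standard_normal((3, 20))
        z[:4] = np.nan
        r = la_score(x, y, z, denominator_policy="total_n")
        assert r.la_score == pytest.approx(naive_la(x, y, z, total_n=True)[0])

    def test_argument_symmetry(self, rng):
        x, y, z = rng.standard_normal((3, 30))
        ref = la_score(x, y, z).la_score
        for p in itertools.permutations((x, y, z)):
            assert la_score(*p).la_score == pytest.approx(ref, abs=1e-14)

    def test_too_few_triples_errors(self):
        with pytest.raises(ValueError, match="triples"):
            la_score([1, 2, np.nan], [1, 2, 3], [np.nan, 2, 3])


class TestScoutZ:
    def test_matches_brute_force_loop(self, random_dataset):
        tds = transform_dataset(random_dataset)
        table = scout_z("G000", "G001", tds, top_k=tds.n_genes)
        x, y = tds.profile("G000"), tds.profile("G001")
        by_gene = {
            e.ids[0]: e.la_score for e in table.top_list
        }
        for g in tds.gene_ids:
            if g in ("G000", "G001"):
                assert g not in by_gene
                continue
            expect, n = naive_la(x, y, tds.profile(g))
            if n >= 3:
                assert by_gene[g] == pytest.approx(expect, abs=1e-10)

    def test_planted_mediator_ranks_first(self, planted_transformed):
        tds, truth = planted_transformed
        (xi, yi, zi), = truth.planted
        table = scout_z(tds.gene_ids[xi], tds.gene_ids[yi], tds, top_k=5)
        assert table.top_list[0].ids[0] == tds.gene_ids[zi]
        assert table.top_list[0].place == 1

    def test_three_gene_dataset_single_candidate(self, rng):
        ds = ExpressionDataset(
            gene_ids=["a", "b", "c"], sample_ids=[f"s{i}" for i in range(6)],
            batch_labels=["B"] * 6, values=rng.standard_normal((3, 6)),
        )
        table = scout_z("a", "b", ds, top_k=20)
        assert table.candidate_count == 1
        assert table.top_list[0].ids[0] == "c" and table.bot_list[0].ids[0] == "c"

    def test_sign_flip_swaps_ends(self, random_dataset):
        tds = transform_dataset(random_dataset)
        t1 = scout_z("G000", "G001", tds, top_k=5)
        flipped = ExpressionDataset(
            gene_ids=tds.gene_ids, sample_ids=tds.sample_ids,
            batch_labels=tds.batch_labels,
            values=np.vstack([tds.values[:2], -tds.values[2:]]),
        )
        t2 = scout_z("G000", "G001", flipped, top_k=5)
        for e1, e2 in zip(t1.top_list, t2.bot_list):
            assert e1.ids == e2.ids
            assert e2.la_score == pytest.approx(-e1.la_score, abs=1e-12)

    def test_tie_break_is_lexicographic(self):
        vals = np.array([
            [1.0, -1.0, 1.0, -1.0],
            [1.0, -1.0, 1.0, -1.0],
            [0.0, 0.0, 0.0, 0.0],   # zz: score 0
            [0.0, 0.0, 0.0, 0.0],   # aa: score 0, should precede zz
        ])
        ds = ExpressionDataset(
            gene_ids=["x", "y", "zz", "aa"], sample_ids=list("pqrs"),
            batch_labels=["B"] * 4, values=vals,
        )
        table = scout_z("x", "y", ds, top_k=2)
        assert [e.ids[0] for e in table.top_list] == ["aa", "zz"]

    def test_bad_args(self, random_dataset):
        with pytest.raises(ValueError):
            scout_z("G000", "G000", random_dataset)
        with pytest.raises(ValueError):
            scout_z("G000", "G001", random_dataset, top_k=0)


class TestSearchPairs:
    def test_matches_brute_force_double_loop(self, random_dataset):
        tds = transform_dataset(random_dataset)
        table = search_pairs("G000", tds, top_k=10**6)
        x = tds.profile("G000")
        got = {e.ids: e.la_score for e in table.top_list}
        others = [g for g in tds.gene_ids if g != "G000"]
        n_checked = 0
        for a, b in itertools.combinations(others, 2):
            expect, n = naive_la(x, tds.profile(a), tds.profile(b))
            if n >= 3:
                key = tuple(sorted((a, b)))
                assert got[key] == pytest.approx(expect, abs=1e-10)
                n_checked += 1
        assert n_checked == table.candidate_count

    def test_three_gene_dataset_single_pair(self, rng):
        ds = ExpressionDataset(
            gene_ids=["a", "b", "c"], sample_ids=[f"s{i}" for i in range(6)],
            batch_labels=["B"] * 6, values=rng.standard_normal((3, 6)),
        )
        table = search_pairs("a", ds, top_k=20)
        assert table.candidate_count == 1
        assert table.top_list[0].ids == ("b", "c")

    def test_planted_pair_leads_single_x_search(self, planted_transformed):
        tds, truth = planted_transformed
        (xi, yi, zi), = truth.planted
        table = search_pairs(tds.gene_ids[xi], tds, top_k=3)
        assert table.top_list[0].ids == tuple(
            sorted((tds.gene_ids[yi], tds.gene_ids[zi]))
        )


class TestLeadSetReport:
    def test_two_gene_lead_set_reduces_to_scout(self, planted_transformed):
        tds, truth = planted_transformed
        (xi, yi, zi), = truth.planted
        leads = [tds.gene_ids[xi], tds.gene_ids[yi]]
        from lascout.inference import PValueConfig
        report = lead_set_report(
            leads, tds, top_k=3, pvalue_cfg=PValueConfig(method="asymptotic")
        )
        table = scout_z(*leads, tds, top_k=3)
        assert [r.z_id for r in report.rows] == [e.ids[0] for e in table.top_list]
        assert [r.place for r in report.rows] == [1, 2, 3]
        assert all(-1 <= r.corr_high <= 1 and -1 <= r.corr_low <= 1 for r in report.rows)

    def test_planted_mediator_leads_every_planted_pair(self):
        from lascout.inference import PValueConfig
        from lascout.synthetic_data import MediationFn, SyntheticSpec, generate_dataset

        m = MediationFn("tanh", 0.9, 2.0)
        spec = SyntheticSpec(
            n_genes=30, batch_sizes=(44, 44),
            planted_triplets=((0, 1, 2, m), (3, 4, 5, m)),
            seed=5,
        )
        ds, truth = generate_dataset(spec)
        tds = transform_dataset(ds)
        for (xi, yi, zi) in truth.planted:
            report = lead_set_report(
                [ds.gene_ids[xi], ds.gene_ids[yi]], tds, top_k=1,
                pvalue_cfg=PValueConfig(method="asymptotic"),
            )
            assert report.rows[0].z_id == ds.gene_ids[zi]
            assert report.rows[0].place == 1
            assert report.rows[0].corr_high > report.rows[0].corr_low

    def test_absent_lead_named_in_error(self, random_dataset):
        with pytest.raises(ValueError, match="G999"):
            lead_set_report(["G000", "G999"], random_dataset)

    def test_shared_top_z_query(self, planted_transformed):
        tds, truth = planted_transformed
        from lascout.inference import PValueConfig
        (xi, yi, zi), = truth.planted
        leads = [tds.gene_ids[i] for i in (xi, yi, 5)]
        report = lead_set_report(
            leads, tds, top_k=10, pvalue_cfg=PValueConfig(method="asymptotic")
        )
        counts = report.shared_top_z()
        assert counts[tds.gene_ids[zi]] >= 1
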