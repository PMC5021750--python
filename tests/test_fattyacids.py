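"""Fatty-acid totals, tissue quotas, species aggregation and rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from epagrowth.datamodel import FattyAcidProfile
from epagrowth.fattyacids import (
    ANALYTES,
    clone_mean_totals,
    clone_quotas,
    fa_totals,
    kruskal_wallis,
    newly_built_biomass_content,
    species_mean_table,
)
from epagrowth.synthetic import (
    DEFAULT_CLONES,
    FA_NEONATE_ANCHORS,
    FA_QUOTA_ANCHORS,
)


def _profile(clone="c1", stage="neonate", mass=480.0, lin=1.0, ala=2.0, ete=3.0,
             epa=4.0, other=10.0):
    return FattyAcidProfile(
        clone, stage, 1, mass,
        {"18:2w6": lin, "18:3w3": ala, "20:3w3": ete, "20:5w3": epa,
         "other": other},
    )


class TestTotals:
    def test_zero_profile(self):
        t = fa_totals(_profile(lin=0, ala=0, ete=0, epa=0, other=0))
        assert all(v == 0 for v in t.values())

    def test_definition_arithmetic(self):
        t = fa_totals(_profile(lin=1, ala=2, ete=3, epa=4, other=10))
        assert t["total_PUFA"] == 10
        assert t["total_w3"] == 9
        assert t["total_FA"] == 20
        assert t["EPA"] == 4

    def test_w3_is_pufa_minus_linoleic(self):
        p = _profile(lin=1.7, ala=0.3, ete=0.9, epa=2.2, other=5.0)
        t = fa_totals(p)
        assert t["total_w3"] == pytest.approx(
            t["total_PUFA"] - p.fa_content["18:2w6"]
        )


class TestTissueQuota:
    def test_homogeneous_tissue(self):
        neo = _profile(stage="neonate", mass=100.0, other=40.0, lin=0, ala=0,
                       ete=0, epa=0)
        d6 = _profile(stage="day6", mass=250.0, other=40.0, lin=0, ala=0, ete=0,
                      epa=0)
        q = newly_built_biomass_content(neo, d6, "total_FA")
        assert q.content_new_biomass == pytest.approx(40.0)
        assert not q.depletion

    def test_worked_arithmetic(self):
        # C0 = 40 at m0 = 100; C6 = 60 at m6 = 300 -> (18000-4000)/200 = 70
        neo = _profile(stage="neonate", mass=100.0, other=40.0, lin=0, ala=0,
                       ete=0, epa=0)
        d6 = _profile(stage="day6", mass=300.0, other=60.0, lin=0, ala=0, ete=0,
                      epa=0)
        q = newly_built_biomass_content(neo, d6, "total_FA")
        assert q.content_new_biomass == pytest.approx(70.0)

    def test_mass_rescaling_invariance(self):
        neo = _profile(stage="neonate", mass=100.0, epa=2.0)
        d6 = _profile(stage="day6", mass=300.0, epa=3.0)
        q1 = newly_built_biomass_content(neo, d6, "EPA").content_new_biomass
        neo2 = _profile(stage="neonate", mass=700.0, epa=2.0)
        d62 = _profile(stage="day6", mass=2100.0, epa=3.0)
        q2 = newly_built_biomass_content(neo2, d62, "EPA").content_new_biomass
        assert q1 == pytest.approx(q2)

    def test_depletion_flag_not_clamped(self):
        neo = _profile(stage="neonate", mass=100.0, epa=10.0)
        d6 = _profile(stage="day6", mass=150.0, epa=1.0)
        q = newly_built_biomass_content(neo, d6, "EPA")
        assert q.content_new_biomass < 0
        assert q.depletion

    def test_no_growth_is_error(self):
        neo = _profile(stage="neonate", mass=300.0)
        d6 = _profile(stage="day6", mass=250.0)
        with pytest.raises(ValueError, match="growth"):
            newly_built_biomass_content(neo, d6, "EPA")

    def test_mismatched_clones_rejected(self):
        with pytest.raises(ValueError, match="different clones"):
            newly_built_biomass_content(
                _profile(clone="a"), _profile(clone="b", stage="day6", mass=600.0),
                "EPA",
            )


class TestSpeciesMeans:
    SPECIES_OF = {c.clone_id: c.species for c in DEFAULT_CLONES}

    def _tidy(self, anchors, analyte_index, analyte):
        return pd.DataFrame(
            [
                {"clone_id": cid, "analyte": analyte,
                 "value": vals[analyte_index]}
                for cid, vals in anchors.items()
            ]
        )

    @pytest.mark.parametrize(
        "anchors, index, analyte, species, expected",
        [
            (FA_QUOTA_ANCHORS, 0, "total_FA", "pulicaria", 89.51),
            (FA_QUOTA_ANCHORS, 0, "total_FA", "magna", 52.30),
            (FA_NEONATE_ANCHORS, 0, "total_FA", "longispina_complex", 41.58),
            (FA_NEONATE_ANCHORS, 2, "total_w3", "longispina_complex", 21.30),
            (FA_NEONATE_ANCHORS, 0, "total_FA", "pulicaria", 40.39),
            (FA_NEONATE_ANCHORS, 0, "total_FA", "magna", 35.00),
        ],
    )
    def test_unweighted_clone_mean_cells(self, anchors, index, analyte, species,
                                         expected):
        table = species_mean_table(self._tidy(anchors, index, analyte),
                                   self.SPECIES_OF)
        row = table[(table.species == species) & (table.analyte == analyte)]
        assert row["mean"].iloc[0] == pytest.approx(expected, abs=0.01)

    def test_single_clone_species_has_blank_se(self):
        tidy = pd.DataFrame(
            [
                {"clone_id": "DlE", "analyte": "EPA", "value": 1.0},
                {"clone_id": "IL-M1-12", "analyte": "EPA", "value": 2.0},
                {"clone_id": "IL-M1-8", "analyte": "EPA", "value": 4.0},
            ]
        )
        table = species_mean_table(tidy, self.SPECIES_OF)
        single = table[table.species == "longispina_complex"]
        assert single["mean"].iloc[0] == 1.0
        assert np.isnan(single["se"].iloc[0])
        double = table[table.species == "magna"]
        assert double["mean"].iloc[0] == pytest.approx(3.0)
        assert double["se"].iloc[0] == pytest.approx(np.std([2, 4], ddof=1) / np.sqrt(2))

    def test_missing_values_reduce_divisor(self):
        tidy = pd.DataFrame(
            [
                {"clone_id": "IL-M1-12", "analyte": "EPA", "value": 2.0},
                {"clone_id": "IL-M1-8", "analyte": "EPA", "value": float("nan")},
                {"clone_id": "FI-N26-8c", "analyte": "EPA", "value": 4.0},
            ]
        )
        table = species_mean_table(tidy, self.SPECIES_OF)
        row = table[table.species == "magna"]
        assert row["mean"].iloc[0] == pytest.approx(3.0)
        assert row["n_clones"].iloc[0] == 2

    def test_unknown_clone_rejected(self):
        tidy = pd.DataFrame([{"clone_id": "??", "analyte": "EPA", "value": 1.0}])
        with pytest.raises(ValueError, match="species mapping"):
            species_mean_table(tidy, self.SPECIES_OF)


class TestQuotaPipeline:
    def test_zero_noise_quotas_reproduce_anchor_totals(self, default_cfg):
        import epagrowth as eg

        profiles = eg.simulate_fattyacids(default_cfg.noise_free())
        quotas = clone_quotas(profiles)
        fa = quotas[(quotas.clone_id == "DpBrS") & (quotas.analyte == "total_FA")]
        assert fa["value"].iloc[0] == pytest.approx(
            FA_QUOTA_ANCHORS["DpBrS"][0], abs=0.05
        )
        epa = quotas[(quotas.clone_id == "IL-M1-8") & (quotas.analyte == "EPA")]
        assert epa["value"].iloc[0] == pytest.approx(
            FA_QUOTA_ANCHORS["IL-M1-8"][3], abs=0.02
        )

    def test_clone_mean_totals_counts_replicates(self, default_cfg):
        import epagrowth as eg

        profiles = eg.simulate_fattyacids(default_cfg)
        tidy = clone_mean_totals(profiles, "neonate")
        assert set(tidy.analyte) == set(ANALYTES)
        assert (tidy.n_replicates == default_cfg.n_fa_replicates).all()


def _kw_oracle(groups):
    """Explicit rank-sum formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_total = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        n = len(g)
        r = ranks[start : start + n]
        h += r.sum() ** 2 / n
        start += n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / tie


class TestKruskalWallis:
    def test_matches_brute_force_rank_oracle(self):
        groups = [[1, 2], [3, 4], [5, 6, 7, 8]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(_kw_oracle(groups), rel=1e-12)
        assert p == pytest.approx(float(chi2.sf(h, 2)), rel=1e-12)

    def test_oracle_agreement_with_ties(self):
        groups = [[1, 1, 2], [2, 2, 3], [3, 4, 4, 4]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(_kw_oracle(groups), rel=1e-12)

    def test_identical_groups_convention(self):
        assert kruskal_wallis([[2.0, 2.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(3 * np.asarray(g)) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12345)
        pvals = [
            kruskal_wallis([rng.normal(size=20) for _ in range(3)])[1]
            for _ in range(400)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
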