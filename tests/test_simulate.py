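"""Generator contracts: determinism, factor structure, phenology, planting."""

import numpy as np
import pandas as pd
import pytest

from nichespace.simulate import (
    _DIM_LATENTS,
    LATENT_NAMES,
    SimConfig,
    generate_community,
    generate_phenology,
    plant_convergent_cluster,
)
from nichespace.traits import TRAIT_NAMES, phenology_stats


def implied_correlation(config, dimension):
    """Closed-form trait-trait correlation within one dimension block.

    Under the factor model log-trait = mu + sigma*(w.z + s*eps) with unit
    latents, corr(t_i, t_j) = w_i.w_j / sqrt((|w_i|^2 + s_i^2)(|w_j|^2 + s_j^2)).
    """
    traits = [t for t in TRAIT_NAMES if config.trait_model[t].dimension == dimension]
    out = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            sa, sb = config.trait_model[a], config.trait_model[b]
            wa, wb = np.array(sa.loadings), np.array(sb.loadings)
            va = wa @ wa + (config.noise_sd * sa.noise_mult) ** 2
            vb = wb @ wb + (config.noise_sd * sb.noise_mult) ** 2
            out.loc[a, b] = out.loc[b, a] = (wa @ wb) / np.sqrt(va * vb)
    return out


class TestGenerateCommunity:
    def test_default_config_echo(self, community):
        table = community.trait_table
        assert len(table.data) == 215
        counts = table.data.groupby(level=1).size()
        assert counts.to_dict() == {"TF": 90, "SF": 70, "WF": 49, "CF": 6}
        families = {r.family for r in community.records}
        assert len(families) <= 55
        genera = {r.genus for r in community.records}
        assert len(genera) <= 116
        table.validate()  # full invariant suite

    def test_eight_shared_species_between_adjacent_sites(self, community):
        ids = pd.Series([r.species_id for r in community.records])
        assert ids.nunique() == 215 - 8
        dup = ids[ids.duplicated()].tolist()
        assert len(dup) == 8

    def test_abundances_above_sampling_threshold(self, community):
        assert all(r.abundance > 20 for r in community.records)

    def test_deterministic_under_seed(self):
        a = generate_community(seed=5)
        b = generate_community(seed=5)
        assert a.trait_table.data.equals(b.trait_table.data)
        assert a.records == b.records
        assert a.latents.equals(b.latents)
        c = generate_community(seed=6)
        assert not a.trait_table.data.equals(c.trait_table.data)

    def test_noise_free_blocks_have_latent_rank(self):
        config = SimConfig(noise_sd=0.0)
        com = generate_community(config, seed=2)
        for dim, latents in _DIM_LATENTS.items():
            traits = [t for t in TRAIT_NAMES if config.trait_model[t].dimension == dim]
            block = com.log_traits[traits].to_numpy()
            rank = np.linalg.matrix_rank(block - block.mean(0), tol=1e-8)
            assert rank <= len(latents)

    def test_empirical_matches_implied_correlation(self):
        config = SimConfig(
            biome_species={"TF": 500},
            noise_sd=0.2,
            biome_shifts=SimConfig().biome_shifts * 0.0,
            latent_correlation=pd.DataFrame(
                np.eye(6), index=list(LATENT_NAMES), columns=list(LATENT_NAMES)
            ),
        )
        com = generate_community(config, seed=3)
        for dim in ("leaf_economy", "mechanical_support", "reproductive_phenology"):
            implied = implied_correlation(config, dim)
            empirical = com.log_traits[implied.index].corr()
            assert np.abs(empirical.to_numpy() - implied.to_numpy()).max() < 0.1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimConfig(noise_sd=-0.1).validate()
        with pytest.raises(ValueError, match="positive semidefinite"):
            R = SimConfig().latent_correlation.copy()
            R.iloc[0, 1] = R.iloc[1, 0] = 2.0
            SimConfig(latent_correlation=R).validate()
        with pytest.raises(ValueError, match="genus"):
            SimConfig(n_genera=10).validate()


class TestPhenologyGeneration:
    def test_windows_valid_and_reproducible(self):
        w1 = generate_phenology(seed=4)
        w2 = generate_phenology(seed=4)
        assert w1 == w2
        for w in w1:
            assert 1 <= w.first_month <= 12 and 1 <= w.last_month <= 12
            assert w.first_month <= w.last_month

    def test_fruiting_starts_at_or_after_flowering(self, community):
        by_sp = {}
        for w in community.windows:
            by_sp.setdefault(w.species_id, {})[w.phase] = w
        for phases in by_sp.values():
            assert phases["fruiting"].first_month >= phases["flowering"].first_month

    def test_windows_track_duration_traits(self, community):
        # month-resolution consistency: window duration correlates strongly
        # with the continuous FLD trait the window was derived from
        flower = {w.species_id: w for w in community.windows if w.phase == "flowering"}
        rows = []
        seen = set()
        for (sp, biome), row in community.trait_table.data.iterrows():
            if sp in seen:
                continue
            seen.add(sp)
            _, duration = phenology_stats(flower[sp])
            rows.append((row.FLD, duration))
        fld, dur = np.array(rows).T
        assert np.corrcoef(np.log10(fld), dur)[0, 1] > 0.8

    def test_duration_latent_drives_duration(self):
        # monotone link: +2 sd duration latent vs -2 sd over 200 draws
        config = SimConfig(biome_species={"TF": 200},
                           biome_shifts=SimConfig().biome_shifts * 0.0)
        hi_shift = config.biome_shifts.copy()
        hi_shift.loc["TF", "phenology_duration"] = 2.0
        lo_shift = hi_shift.copy()
        lo_shift.loc["TF", "phenology_duration"] = -2.0
        hi = generate_community(SimConfig(biome_species={"TF": 200},
                                          biome_shifts=hi_shift), seed=8)
        lo = generate_community(SimConfig(biome_species={"TF": 200},
                                          biome_shifts=lo_shift), seed=8)
        def mean_duration(com):
            return np.mean([phenology_stats(w)[1] for w in com.windows
                            if w.phase == "flowering"])
        assert mean_duration(hi) > mean_duration(lo)


class TestPlantedCluster:
    ISOLATED = np.full(6, 2.2)  # latent corner far from the community mass

    def test_planted_cluster_ratio_one(self, community):
        import warnings
        from nichespace.comparison import combined_space
        from nichespace.periodicity import bin_species, cell_index

        planted = plant_convergent_cluster(
            community, n_species=5, n_families=5, radius=0.05,
            target=self.ISOLATED, seed=21,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pooled = combined_space(planted.per_biome_tables())
        xy = pooled.xy.loc[planted.planted["species"]]
        cells = {cell_index(x, y, 0.5) for x, y in xy.to_numpy()}
        assert len(cells) == 1
        grid = bin_species(pooled, planted.families)
        plot = grid[cells.pop()]
        assert plot.n_species == 5 and plot.n_families == 5

    def test_radius_zero_collapses_distances(self, community):
        planted = plant_convergent_cluster(
            community, n_species=4, n_families=2, radius=0.0,
            target=self.ISOLATED, seed=22,
        )
        logs = planted.log_traits.loc[planted.planted["species"]]
        assert np.allclose(logs.to_numpy() - logs.to_numpy()[0], 0.0, atol=1e-12)

    def test_family_reassignment_counts(self, community):
        planted = plant_convergent_cluster(
            community, n_species=6, n_families=3, radius=0.02, seed=23
        )
        fams = planted.families.loc[planted.planted["species"]]
        assert fams.nunique() == 3

    def test_infeasible_counts_rejected(self, community):
        with pytest.raises(ValueError, match="n_families"):
            plant_convergent_cluster(community, n_species=3, n_families=5)
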