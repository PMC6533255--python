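import numpy as np
import pandas as pd
import pytest

from ecostrategy import (
    SynthSpec,
    chained_impute,
    complete_cases,
    generate_trait_table,
    generate_tree,
    inject_missingness,
    phylo_eigenvectors,
    read_tree,
)
from ecostrategy.impute import impute_table
from ecostrategy.io import PatristicDistances


def balanced_two_clade_tree(tmp_path, n_per_clade=4, inner=5.0, outer=0.5):
    left = "(" + ",".join(f"L{i}:{outer}" for i in range(n_per_clade)) + f"):{inner}"
    right = "(" + ",".join(f"R{i}:{outer}" for i in range(n_per_clade)) + f"):{inner}"
    p = tmp_path / "clades.nwk"
    p.write_text(f"({left},{right});\n")
    return read_tree(p)


class TestPhyloEigenvectors:
    def test_first_axis_separates_clades(self, tmp_path):
        pd_ = balanced_two_clade_tree(tmp_path)
        ev = phylo_eigenvectors(pd_, k=3)
        e1 = ev.data["ev1"]
        left = e1[[l.startswith("L") for l in ev.data.index]]
        right = e1[[l.startswith("R") for l in ev.data.index]]
        assert (np.sign(left) == np.sign(left.iloc[0])).all()
        assert (np.sign(right) == -np.sign(left.iloc[0])).all()

    def test_columns_orthogonal_and_centered(self, tmp_path):
        nwk = generate_tree(20, seed=1)
        p = tmp_path / "t.nwk"
        p.write_text(nwk)
        ev = phylo_eigenvectors(read_tree(p), k=6).data.to_numpy()
        G = ev.T @ ev
        assert np.allclose(G - np.diag(np.diagonal(G)), 0, atol=1e-8)
        assert np.allclose(ev.mean(axis=0), 0, atol=1e-8)

    def test_star_tree_degenerate_spectrum_is_deterministic(self):
        n = 6
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        pd_ = PatristicDistances([f"s{i}" for i in range(n)], m)
        a = phylo_eigenvectors(pd_, k=3).data
        b = phylo_eigenvectors(pd_, k=3).data
        pd.testing.assert_frame_equal(a, b)
        # centered constant matrix: all nonzero eigenvalues equal
        from ecostrategy.traits import DistanceMatrix, pcoa

        res = pcoa(DistanceMatrix(pd_.labels, m), n_axes=n - 1)
        nz = res.eigenvalues[res.eigenvalues > 1e-9]
        assert np.allclose(nz, nz[0])

    def test_k_must_be_less_than_n(self, tmp_path):
        pd_ = balanced_two_clade_tree(tmp_path)
        with pytest.raises(ValueError):
            phylo_eigenvectors(pd_, k=8)


def correlated_matrix(n, seed, rho=0.7):
    rng = np.random.default_rng(seed)
    C = np.full((5, 5), rho)
    np.fill_diagonal(C, 1.0)
    X = rng.multivariate_normal(np.zeros(5), C, size=n)
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(n)],
        columns=["mass", "litter", "habitat", "generation", "diet"],
    )


def mask_mcar(df, frac, seed, skip=("mass",)):
    rng = np.random.default_rng(seed)
    out = df.copy()
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    for c in df.columns:
        if c in skip:
            continue
        m = rng.random(len(df)) < frac
        out.loc[m, c] = np.nan
        mask[c] = m
    return out, mask


class TestChainedImpute:
    def test_complete_input_returns_identical_copies(self):
        df = correlated_matrix(80, seed=2)
        ens = chained_impute(df, m=3, n_iter=2, seed=1)
        for mem in ens.members:
            pd.testing.assert_frame_equal(mem, df)

    def test_observed_cells_identical_across_members(self):
        df = correlated_matrix(200, seed=3)
        masked, mask = mask_mcar(df, 0.2, seed=3)
        ens = chained_impute(masked, m=4, n_iter=3, seed=5)
        obs = ~mask
        for mem in ens.members[1:]:
            assert np.allclose(
                mem.to_numpy()[obs.to_numpy()], ens.members[0].to_numpy()[obs.to_numpy()]
            )

    def test_pmm_values_come_from_observed_donors(self):
        df = correlated_matrix(200, seed=4)
        masked, mask = mask_mcar(df, 0.25, seed=4)
        ens = chained_impute(masked, m=2, n_iter=3, seed=6)
        for c in df.columns:
            donors = set(masked[c].dropna())
            for mem in ens.members:
                imputed = mem.loc[mask[c], c]
                assert all(v in donors for v in imputed)

    def test_imputation_distribution_not_degenerate(self):
        df = correlated_matrix(300, seed=7)
        masked, mask = mask_mcar(df, 0.3, seed=7)
        ens = chained_impute(masked, m=8, n_iter=4, seed=8)
        cells = np.argwhere(mask.to_numpy())
        var = np.var(
            [[mem.to_numpy()[i, j] for mem in ens.members] for i, j in cells[:50]],
            axis=1,
        )
        assert (var > 0).mean() > 0.8

    def test_beats_mean_fill_on_correlated_traits(self):
        wins = 0
        trials = 10
        for s in range(trials):
            df = correlated_matrix(250, seed=100 + s)
            masked, mask = mask_mcar(df, 0.2, seed=100 + s)
            ens = chained_impute(masked, m=3, n_iter=5, seed=200 + s)
            mean_member = sum(ens.members) / len(ens.members)
            fill = masked.fillna(masked.mean())
            m = mask.to_numpy()
            rmse_mice = np.sqrt(np.mean((mean_member.to_numpy()[m] - df.to_numpy()[m]) ** 2))
            rmse_fill = np.sqrt(np.mean((fill.to_numpy()[m] - df.to_numpy()[m]) ** 2))
            wins += rmse_mice < rmse_fill
        assert wins >= 9

    def test_pooled_correlation_closer_than_complete_case(self):
        # parameter recovery at 40% missingness
        df = correlated_matrix(600, seed=42, rho=0.6)
        masked, mask = mask_mcar(df, 0.4, seed=42)
        ens = chained_impute(masked, m=5, n_iter=5, seed=43)
        truth = np.full((5, 5), 0.6)
        np.fill_diagonal(truth, 1.0)
        pooled = np.mean([np.corrcoef(m.to_numpy().T) for m in ens.members], axis=0)
        cc = masked.dropna()
        cc_corr = np.corrcoef(cc.to_numpy().T)
        assert np.linalg.norm(pooled - truth) < np.linalg.norm(cc_corr - truth)

    def test_too_few_observed_values_rejected(self):
        df = correlated_matrix(40, seed=9)
        df.iloc[:25, 1] = np.nan
        with pytest.raises(ValueError, match="observed values"):
            chained_impute(df, m=2, n_iter=2, seed=1)

    def test_deterministic_given_seed(self):
        df = correlated_matrix(150, seed=10)
        masked, _ = mask_mcar(df, 0.3, seed=10)
        a = chained_impute(masked, m=2, n_iter=3, seed=77)
        b = chained_impute(masked, m=2, n_iter=3, seed=77)
        for ma, mb in zip(a.members, b.members):
            pd.testing.assert_frame_equal(ma, mb)


class TestCompleteCases:
    def test_complete_table_unchanged(self, complete_table):
        out = complete_cases(complete_table)
        assert out.n_species == complete_table.n_species

    def test_species_with_any_missing_trait_dropped(self, missing_table):
        masked, _ = missing_table
        out = complete_cases(masked)
        assert out.n_species < masked.n_species
        assert all(v == 0 for v in out.missing_counts().values())

    def test_empty_result_is_error(self, complete_table):
        df = complete_table.df.copy()
        df["litter_clutch_size"] = np.nan
        from ecostrategy import TraitTable

        with pytest.raises(ValueError, match="complete cases"):
            complete_cases(TraitTable(df))


class TestImputeTable:
    def test_classwise_imputation_covers_all_species(self, missing_table):
        masked, _ = missing_table
        from ecostrategy.traits import transform_traits
        from ecostrategy import diet_axis

        scores, _, _ = diet_axis(masked)
        transformed = transform_traits(masked, scores)
        taxon = pd.Series(masked.df["taxon_class"].to_numpy(), index=transformed.index)
        ens = impute_table(transformed, taxon, m=2, n_iter=2, seed=3)
        for mem in ens.members:
            assert not mem.isna().any().any()
            assert list(mem.index) == list(transformed.index)
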