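"""Mixed-model equations: assembly, solvers, reductions, equivalences."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import grm
from ssgblup import hmatrix as hm
from ssgblup import mme
from ssgblup import pedigree as pm
from ssgblup.io_formats import RawPedigree, write_triplets
from ssgblup.simulate import SimConfig, simulate_population

from conftest import fullrank_genotypes, gblup_frame


def _identity_struct(ids):
    return mme.Covstruct(inv=np.eye(len(ids)), order=len(ids),
                         level_index={a: i for i, a in enumerate(ids)})


class TestBuildMme:
    def test_small_system_shape_and_lambda(self):
        data = pd.DataFrame({"animal": ["1", "2", "3"], "sex": ["1", "2", "1"],
                             "y": [1.0, 2.0, 3.0]})
        model = mme.ModelSpec(trait="y", fixed_effects=["sex"], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 0.5)],
                              residual_variance=1.0)
        sys = mme.build_mme(model, data, [_identity_struct(["1", "2", "3"])])
        assert sys.order == 5
        L = sys.to_dense()
        # animal block = W'W + lambda I with lambda = 1/0.5 = 2
        assert np.allclose(np.diag(L)[2:], 1.0 + 2.0)
        assert sys.eqmap[:2] == [(1, 1), (1, 2)]

    def test_correction_only_on_genotyped_equations(self):
        ped = pm.renumber(RawPedigree(
            [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "2")]
        ))
        gi = np.array([2, 3])
        ainv = pm.build_Ainv(ped)
        a22inv = np.linalg.inv(pm.build_A22(ped, gi))
        ginv = np.linalg.inv(np.array([[1.1, 0.4], [0.4, 1.1]]))
        hinv = hm.build_Hinv(ainv, a22inv, ginv, gi)
        data = pd.DataFrame({"animal": ["1", "2", "3", "4"], "y": [1.0, 2, 3, 4]})
        model = mme.ModelSpec(trait="y", fixed_effects=[], animal="animal",
                              genetic_effects=[mme.GeneticEffect("ssgblup", 1.0)],
                              residual_variance=1.0)
        struct = mme.Covstruct(inv=hinv, order=4,
                               level_index={a: i - 1 for a, i in ped.xref.items()})
        sys = mme.build_mme(model, data, [struct])
        L = sys.to_dense()
        base = ainv.toarray() + np.eye(4)
        delta = L - base
        nong = [0, 1]
        assert np.abs(delta[np.ix_(nong, nong)]).max() == 0.0
        assert np.abs(delta[np.ix_(gi, gi)]).max() > 0.0

    def test_missing_animal_rejected(self):
        data = pd.DataFrame({"animal": ["1", "9"], "y": [1.0, 2.0]})
        model = mme.ModelSpec(trait="y", fixed_effects=[], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 1.0)],
                              residual_variance=1.0)
        with pytest.raises(mme.MmeError, match="'9'"):
            mme.build_mme(model, data, [_identity_struct(["1", "2"])])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(mme.MmeError, match="positive"):
            mme.GeneticEffect("gblup", 0.0)

    def test_two_user_structures_match_dense_oracle(self, tmp_path):
        """Two independent random effects over the same animals (saved
        covariance-inverse files) reproduce a hand-built dense MME, and the
        per-animal total is the sum of the two solutions."""
        rng = np.random.default_rng(8)
        raw = RawPedigree(
            [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "2"),
             ("5", "3", "4")]
        )
        ped = pm.renumber(raw)
        n = ped.n
        K1 = pm.build_Ainv(ped).toarray()
        K2 = np.eye(n)
        f1, f2 = tmp_path / "h1.txt", tmp_path / "h2.txt"
        write_triplets(K1, f1)
        write_triplets(K2, f2)
        y = rng.normal(size=n) + 1.0
        data = pd.DataFrame({"animal": [str(i) for i in range(1, n + 1)],
                             "mu": ["1"] * n, "y": y})
        cfg = dict(method="user_file", data=data, pedigree=raw,
            trait="y", fixed_effects=["mu"], animal="animal",
            residual_variance=0.5, solver="direct",
            user_files=[{"file": str(f1), "variance": 0.3},
                        {"file": str(f2), "variance": 0.1}])
        res = mme.run_evaluation(cfg)
        u1 = res.solutions.effect(2)
        u2 = res.solutions.effect(3)
        lam1, lam2 = 0.5 / 0.3, 0.5 / 0.1
        X = np.ones((n, 1))
        W = np.eye(n)
        LHS = np.block([
            [X.T @ X, X.T @ W, X.T @ W],
            [W @ X, W + K1 * lam1, W],
            [W @ X, W, W + K2 * lam2],
        ])
        RHS = np.concatenate([X.T @ y, y, y])
        ref = np.linalg.solve(LHS, RHS)
        assert np.abs(u1 - ref[1:1 + n]).max() < 1e-8
        assert np.abs(u2 - ref[1 + n:]).max() < 1e-8
        total = u1 + u2  # combined genetic effect, one value per animal
        assert total.shape == (n,)


class TestSolvers:
    def test_direct_diagonal(self):
        data = pd.DataFrame({"animal": ["1", "2"], "y": [2.0, 4.0]})
        model = mme.ModelSpec(trait="y", fixed_effects=[], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 1.0)],
                              residual_variance=1.0)
        sys = mme.build_mme(model, data, [_identity_struct(["1", "2"])])
        sol = mme.solve_direct(sys)
        assert np.allclose(sol.values, sys.rhs / sys.to_dense().diagonal())

    def test_direct_vs_numpy(self):
        rng = np.random.default_rng(1)
        ids = [str(i) for i in range(20)]
        data = pd.DataFrame({"animal": ids, "sex": rng.integers(1, 3, 20).astype(str),
                             "y": rng.normal(size=20)})
        model = mme.ModelSpec(trait="y", fixed_effects=["sex"], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 0.7)],
                              residual_variance=0.4)
        sys = mme.build_mme(model, data, [_identity_struct(ids)])
        sol = mme.solve_direct(sys)
        assert np.abs(sol.values - np.linalg.solve(sys.to_dense(), sys.rhs)).max() < 1e-10

    def test_duplicated_fixed_effect_singular(self):
        data = pd.DataFrame({"animal": ["1", "2", "3"],
                             "a": ["1", "2", "1"], "b": ["1", "2", "1"],
                             "y": [1.0, 2.0, 3.0]})
        model = mme.ModelSpec(trait="y", fixed_effects=["a", "b"], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 1.0)],
                              residual_variance=1.0)
        sys = mme.build_mme(model, data, [_identity_struct(["1", "2", "3"])])
        with pytest.raises(mme.MmeError, match="singular"):
            mme.solve_direct(sys)

    def test_pcg_zero_rhs(self):
        data = pd.DataFrame({"animal": ["1", "2"], "y": [0.0, 0.0]})
        model = mme.ModelSpec(trait="y", fixed_effects=[], animal="animal",
                              genetic_effects=[mme.GeneticEffect("gblup", 1.0)],
                              residual_variance=1.0)
        sys = mme.build_mme(model, data, [_identity_struct(["1", "2"])])
        assert np.array_equal(mme.solve_pcg(sys).values, np.zeros(2))

    def test_pcg_matches_direct_on_ssgblup(self, small_dataset):
        cfg = small_dataset.eval_config("ssgblup")
        direct = mme.run_evaluation({**cfg, "solver": "direct"})
        pcg = mme.run_evaluation({**cfg, "solver": "pcg"})
        assert pcg.solutions.converged
        assert np.abs(pcg.solutions.values - direct.solutions.values).max() < 1e-8

    def test_loose_tolerance_fewer_iterations(self, small_dataset):
        cfg = small_dataset.eval_config("ssgblup")
        tight = mme.run_evaluation({**cfg, "tol": 1e-12})
        loose = mme.run_evaluation({**cfg, "tol": 1e-6})
        assert loose.solutions.iterations < tight.solutions.iterations
        assert np.abs(loose.solutions.values - tight.solutions.values).max() < 1e-3


class TestReductions:
    def test_ssgblup_with_no_genotyped_is_blup(self, small_dataset):
        ds = small_dataset
        blup = mme.run_evaluation(ds.eval_config("blup", solver="direct"))
        ped = blup.ped
        ainv = pm.build_Ainv(ped)
        hinv = hm.build_Hinv(ainv, np.zeros((0, 0)), np.zeros((0, 0)),
                             np.array([], dtype=int))
        model = mme.ModelSpec(
            trait="phenotype", fixed_effects=["sex"], animal="animal",
            genetic_effects=[mme.GeneticEffect("ssgblup",
                                               ds.config.genetic_variance)],
            residual_variance=ds.config.residual_variance)
        data = ds.phenotypes.copy()
        data.columns = ["animal", "sex", "phenotype", "tbv", "generation"]
        struct = mme.Covstruct(inv=hinv, order=ped.n,
                               level_index={a: i - 1 for a, i in ped.xref.items()})
        sol = mme.solve_direct(mme.build_mme(model, data, [struct]))
        assert np.abs(sol.values - blup.solutions.values).max() < 1e-10

    def test_ssgblup_all_genotyped_founder_pedigree_is_gblup(self):
        rng = np.random.default_rng(4)
        n, m = 30, 120
        gset, pf = fullrank_genotypes(rng, n, m)
        data = gblup_frame(rng, gset)
        ped = RawPedigree([(a, "0", "0") for a in gset.ids])
        common = dict(data=data, genotypes=gset, pedigree=ped, trait="y",
                      fixed_effects=["sex"], animal="animal",
                      genetic_variance=0.4, residual_variance=0.6,
                      no_quality_control=True, solver="direct")
        ss = mme.run_evaluation({**common, "method": "ssgblup"})
        gb = mme.run_evaluation({**common, "method": "gblup"})
        # compare animal solutions via IDs (orderings differ)
        ss_u = dict(zip(ss.ped.original_ids, ss.gebv))
        gb_u = dict(zip(gb.gset.ids, gb.gebv))
        diff = max(abs(ss_u[a] - gb_u[a]) for a in gset.ids)
        assert diff < 1e-8

    def test_solutions_invariant_to_pedigree_permutation(self, small_dataset):
        ds = small_dataset
        base = mme.run_evaluation(ds.eval_config("ssgblup", solver="direct"))
        rec = list(ds.pedigree.records)
        np.random.default_rng(0).shuffle(rec)
        shuffled = mme.run_evaluation(
            ds.eval_config("ssgblup", solver="direct",
                           pedigree=RawPedigree(rec)))
        u1 = dict(zip(base.ped.original_ids, base.gebv))
        u2 = dict(zip(shuffled.ped.original_ids, shuffled.gebv))
        diff = max(abs(u1[a] - u2[a]) for a in u1)
        assert diff < 1e-8


class TestGblupSnpBlupEquivalence:
    def test_gebv_equal_snp_blup(self):
        rng = np.random.default_rng(7)
        n, m = 40, 200
        gset, pf = fullrank_genotypes(rng, n, m)
        data = gblup_frame(rng, gset)
        cfg = dict(method="gblup", data=data, genotypes=gset, trait="y",
                   fixed_effects=["sex"], animal="animal",
                   genetic_variance=0.4, residual_variance=0.6,
                   tuned_g="none", alpha_beta=(1.0, 0.0),
                   base_frequencies=pf, no_quality_control=True,
                   solver="direct")
        res = mme.run_evaluation(cfg)
        Z = res.Z
        s2a = 0.4 * res.grm.k
        sex = data["sex"].to_numpy()
        X = np.stack([(sex == "1"), (sex == "2")], axis=1).astype(float)
        y = data["y"].to_numpy()
        LHS = np.block([[X.T @ X, X.T @ Z],
                        [Z.T @ X, Z.T @ Z + np.eye(m) * 0.6 / s2a]])
        a_snp = np.linalg.solve(LHS, np.concatenate([X.T @ y, Z.T @ y]))[2:]
        assert np.abs(res.gebv - Z @ a_snp).max() < 1e-6


class TestAccuracyGain:
    def test_ssgblup_not_worse_than_blup_for_masked_juveniles(self):
        """Masked genotyped juveniles: genomic information should help."""
        from ssgblup.simulate import mask_phenotypes

        gains = []
        for seed in (21, 22, 23):
            cfg = SimConfig(n_founders=150, n_generations=3, n_offspring=150,
                            n_sires=15, n_dams=75, n_snps=800, n_qtl=40,
                            seed=seed, genotyped_generations=(2, 3))
            ds = simulate_population(cfg)
            masked = mask_phenotypes(ds, ("generation", 3))
            ss = mme.run_evaluation(masked.eval_config("ssgblup"))
            bl = mme.run_evaluation(masked.eval_config("blup"))
            tr = ds.truth.set_index("animal")
            ids = [a for a in ds.genotypes.ids
                   if int(tr.loc[a, "generation"]) == 3]
            idx = [ss.ped.xref[a] - 1 for a in ids]
            tb = tr.loc[ids, "tbv"].to_numpy()
            gains.append(np.corrcoef(ss.gebv[idx], tb)[0, 1]
                         - np.corrcoef(bl.gebv[idx], tb)[0, 1])
        assert np.mean(gains) > 0
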