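"""H and H⁻¹ assembly, τ/ω scaling, and unknown-parent-group couplings."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import grm
from ssgblup import hmatrix as hm
from ssgblup import mme
from ssgblup import pedigree as pm
from ssgblup.io_formats import RawPedigree

from conftest import random_pedigree


def _instance(seed=0, n=20, n_gen=5, m=80):
    """Random pedigree + genotypes for some animals, blended tuned G."""
    rng = np.random.default_rng(seed)
    ped = pm.renumber(random_pedigree(rng, n))
    gi = np.sort(rng.choice(ped.n, n_gen, replace=False))
    pf = rng.uniform(0.2, 0.8, m)
    M = rng.binomial(2, pf, size=(n_gen, m)).astype(float)
    gset = grm.GenotypeSet(ids=[str(i) for i in gi], M=M)
    p = grm.allele_frequencies(gset)
    G = grm.build_G(grm.center(gset, p), p, ids=gset.ids)
    A = pm.build_A(ped)
    a22 = pm.build_A22(ped, gi)
    G = grm.blend(grm.tune(G, a22, "type2"), a22, 0.95)
    return ped, gi, A, a22, G


class TestBuildH:
    def test_g_equals_a22_gives_a(self):
        ped, gi, A, a22, _ = _instance()
        dummy = grm.Grm(values=a22, ids=[], k=1.0, p=np.array([0.5]),
                        weights=np.array([1.0]))
        assert np.abs(hm.build_H(A, a22, dummy, gi) - A).max() < 1e-12

    def test_genotyped_block_is_g(self):
        ped, gi, A, a22, G = _instance(1)
        H = hm.build_H(A, a22, G, gi)
        assert np.array_equal(H[np.ix_(gi, gi)], G.values)

    def test_trio_offdiagonal_block_by_hand(self):
        # one genotyped animal: H12 = A12 A22⁻¹ G reduces to scalar algebra
        ped = pm.renumber(RawPedigree([("C", "S", "D"), ("S", "0", "0"),
                                       ("D", "0", "0")]))
        A = pm.build_A(ped)
        gi = np.array([ped.xref["C"] - 1])
        a22 = A[np.ix_(gi, gi)]  # [[1.0]]
        gval = np.array([[1.3]])
        dummy = grm.Grm(values=gval, ids=["C"], k=1.0, p=np.array([0.5]),
                        weights=np.array([1.0]))
        H = hm.build_H(A, a22, dummy, gi)
        s = ped.xref["S"] - 1
        assert H[s, gi[0]] == pytest.approx(A[s, gi[0]] / a22[0, 0] * 1.3)

    def test_h_psd_when_g_psd(self):
        for seed in range(3):
            ped, gi, A, a22, G = _instance(seed)
            H = hm.build_H(A, a22, G, gi)
            assert np.linalg.eigvalsh(H).min() > -1e-8


class TestBuildHinv:
    def test_matches_dense_inverse_of_h(self):
        ped, gi, A, a22, G = _instance(2)
        H = hm.build_H(A, a22, G, gi)
        ainv = pm.build_Ainv(ped)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        hinv = hm.build_Hinv(ainv, a22inv, G.inverse(), gi)
        assert np.abs(hinv.to_dense() - np.linalg.inv(H)).max() < 1e-8

    def test_empty_genotyped_set_is_ainv(self):
        ped = pm.renumber(random_pedigree(np.random.default_rng(3), 15))
        ainv = pm.build_Ainv(ped)
        hinv = hm.build_Hinv(ainv, np.zeros((0, 0)), np.zeros((0, 0)),
                             np.array([], dtype=int))
        assert np.abs(hinv.to_dense() - ainv.toarray()).max() == 0.0

    def test_unit_tau_omega_is_default_assembly(self):
        ped, gi, A, a22, G = _instance(4)
        ainv = pm.build_Ainv(ped)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        ginv = G.inverse()
        base = hm.build_Hinv(ainv, a22inv, ginv, gi)
        scaled = hm.build_Hinv(ainv, a22inv, ginv, gi,
                               hm.HinvOptions(tau=1.0, omega=1.0))
        assert np.array_equal(base.correction, scaled.correction)

    def test_tau_omega_scale_the_correction(self):
        ped, gi, A, a22, G = _instance(5)
        ainv = pm.build_Ainv(ped)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        ginv = G.inverse()
        out = hm.build_Hinv(ainv, a22inv, ginv, gi,
                            hm.HinvOptions(tau=1.5, omega=0.7))
        assert np.allclose(out.correction, 1.5 * ginv - 0.7 * a22inv)

    def test_matvec_matches_dense(self):
        ped, gi, A, a22, G = _instance(6)
        ainv = pm.build_Ainv(ped)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        hinv = hm.build_Hinv(ainv, a22inv, G.inverse(), gi)
        v = np.random.default_rng(0).normal(size=ped.n)
        assert np.allclose(hinv.matvec(v), hinv.to_dense() @ v)

    def test_triplet_export_round_trip(self, tmp_path):
        from ssgblup.io_formats import read_triplets

        ped, gi, A, a22, G = _instance(7)
        ainv = pm.build_Ainv(ped)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        hinv = hm.build_Hinv(ainv, a22inv, G.inverse(), gi)
        hinv.save(tmp_path / "Hinv.txt")
        back = read_triplets(tmp_path / "Hinv.txt", order=ped.n).toarray()
        assert np.abs(back - hinv.to_dense()).max() < 1e-9


UPG_RECORDS = [
    ("1", "-1", "-1"), ("2", "-1", "-2"), ("3", "0", "-2"), ("4", "0", "0"),
    ("5", "1", "2"), ("6", "1", "3"), ("7", "4", "2"), ("8", "5", "6"),
    ("9", "5", "7"), ("10", "8", "9"),
]


class TestQ2:
    def test_both_parents_in_group(self):
        ped = pm.renumber(RawPedigree(UPG_RECORDS))
        q2 = hm.build_Q2(ped, np.array([ped.xref["1"] - 1]))
        assert np.allclose(q2, [[1.0, 0.0]])

    def test_fully_pedigreed_zero_row(self):
        ped = pm.renumber(RawPedigree(UPG_RECORDS))
        q2 = hm.build_Q2(ped, np.array([ped.xref["4"] - 1]))
        assert np.allclose(q2, [[0.0, 0.0]])

    def test_half_fraction(self):
        ped = pm.renumber(RawPedigree(UPG_RECORDS))
        # animal 3: sire fully unknown (no group), dam in group 2
        q2 = hm.build_Q2(ped, np.array([ped.xref["3"] - 1]))
        assert np.allclose(q2, [[0.0, 0.5]])

    def test_row_sums_at_most_one(self):
        ped = pm.renumber(RawPedigree(UPG_RECORDS))
        q2 = hm.build_Q2(ped, np.arange(ped.n))
        assert (q2.sum(axis=1) <= 1.0 + 1e-12).all()
        assert (q2 >= 0).all()

    def test_no_upg_error(self, trio):
        ped = pm.renumber(trio)
        with pytest.raises(hm.HmatrixError, match="groups"):
            hm.build_Q2(ped, np.array([0]))


class TestApplyUpg:
    def _pieces(self, seed=3):
        rng = np.random.default_rng(seed)
        ped = pm.renumber(RawPedigree(UPG_RECORDS))
        gen_ids = ["6", "7", "8", "9", "10"]
        gi = np.array([ped.xref[a] - 1 for a in gen_ids])
        m = 60
        pf = rng.uniform(0.2, 0.8, m)
        M = rng.binomial(2, pf, (len(gen_ids), m)).astype(float)
        gset = grm.GenotypeSet(ids=gen_ids, M=M)
        p = grm.allele_frequencies(gset)
        G = grm.blend(grm.build_G(grm.center(gset, p), p, ids=gen_ids),
                      pm.build_A22(ped, gi), 0.95)
        ainv_upg = pm.build_Ainv(ped, upg=True)
        ainv = pm.build_Ainv(ped, upg=False)
        a22inv = pm.build_A22inv_indirect(ainv, gi)
        return ped, gi, G, ainv_upg, a22inv, rng

    def test_zero_q2_changes_nothing(self):
        ped, gi, G, ainv_upg, a22inv, rng = self._pieces()
        ginv = G.inverse()
        hinv = hm.build_Hinv(ainv_upg, a22inv, ginv, gi)
        out = hm.apply_upg(hinv, ginv, a22inv, np.zeros((gi.size, ped.upg_count)))
        dense = out.to_dense()
        base = hinv.to_dense()
        assert np.abs(dense - base).max() < 1e-12

    def test_pedigree_only_scaling_drops_genomic_coupling(self):
        ped, gi, G, ainv_upg, a22inv, rng = self._pieces()
        ginv = G.inverse()
        q2 = hm.build_Q2(ped, gi)
        hinv = hm.build_Hinv(ainv_upg, a22inv, ginv, gi)
        out = hm.apply_upg(hinv, ginv, a22inv, q2,
                           hm.HinvOptions(tau_q2=0.0, omega_q2=1.0))
        ng = gi.size
        coupling = out.correction[:ng, ng:]
        assert np.allclose(coupling, a22inv @ q2)  # -(-A22⁻¹)Q2, no G⁻¹ term

    def test_solutions_match_explicit_qp_transform(self):
        """Eq-55-style assembly == dense MME fitting groups as covariates."""
        ped, gi, G, ainv_upg, a22inv, rng = self._pieces()
        n, g = ped.n, ped.upg_count
        ginv = G.inverse()
        q2 = hm.build_Q2(ped, gi)
        hinv = hm.apply_upg(hm.build_Hinv(ainv_upg, a22inv, ginv, gi),
                            ginv, a22inv, q2)
        y = rng.normal(size=n) + 3.0
        data = pd.DataFrame({"animal": [str(i) for i in range(1, n + 1)],
                             "mu": ["1"] * n, "y": y})
        model = mme.ModelSpec(trait="y", fixed_effects=["mu"], animal="animal",
                              genetic_effects=[mme.GeneticEffect("ssgblup", 0.5)],
                              residual_variance=0.5)
        struct = mme.Covstruct(inv=hinv, order=n + g,
                               level_index={a: i - 1 for a, i in ped.xref.items()})
        sol = mme.solve_direct(mme.build_mme(model, data, [struct]))
        u_star, g_hat = sol.values[1:1 + n], sol.values[1 + n:]

        # oracle: dense H (relationship form), groups as fixed covariates
        A = pm.build_A(ped)
        a22 = pm.build_A22(ped, gi)
        H = hm.build_H(A, a22, G, gi)
        Qfull = np.zeros((n, g))
        for i in range(n):
            for code in (ped.sire[i], ped.dam[i]):
                if code > 0:
                    Qfull[i] += 0.5 * Qfull[code - 1]
                elif code < 0:
                    Qfull[i, -code - 1] += 0.5
        T = np.hstack([np.ones((n, 1)), Qfull])
        LHS = np.block([[T.T @ T, T.T], [T, np.eye(n) + np.linalg.inv(H)]])
        RHS = np.concatenate([T.T @ y, y])
        ref = np.linalg.solve(LHS, RHS)
        g_ref, u_ref = ref[1:1 + g], ref[1 + g:]
        assert np.abs(g_hat - g_ref).max() < 1e-9
        assert np.abs(u_star - (u_ref + Qfull @ g_ref)).max() < 1e-9

    def test_dimension_mismatch(self):
        ped, gi, G, ainv_upg, a22inv, rng = self._pieces()
        ginv = G.inverse()
        hinv = hm.build_Hinv(ainv_upg, a22inv, ginv, gi)
        with pytest.raises(hm.HmatrixError, match="rows"):
            hm.apply_upg(hinv, ginv, a22inv, np.zeros((2, ped.upg_count)))
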