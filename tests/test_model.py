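"""Record I/O, design construction, reparameterization, MME assembly."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from calvease.liability import Thresholds
from calvease.model import (
    RecordTable,
    SMGS_COMPONENTS,
    SMGS_THRESHOLDS,
    VarianceComponents,
    assemble_mme,
    build_design,
    read_records,
    reparameterize_smgs_to_smat,
)
from calvease.pedigree import a_inverse, build_pedigree

HEADER = "sire,dam,mgs,hys,ys,breed,parity,sex,score\n"


def _read(rows):
    return read_records(io.StringIO(HEADER + "\n".join(rows) + "\n"))


class TestReadRecords:
    def test_valid_rows_kept(self):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1"] * 5)
        assert len(rt) == 5

    def test_out_of_range_score_dropped(self):
        with pytest.warns(UserWarning, match="dropped 1"):
            rt = _read(["S,D,G,h1,y1,HO,1,1,5", "S,D,G,h1,y1,HO,1,1,2"])
        assert len(rt) == 1 and rt.df["score"].iloc[0] == 2

    def test_missing_dam_with_mgs_retained(self):
        rt = _read(["S,0,G,h1,y1,HO,1,1,3"])
        assert len(rt) == 1

    def test_missing_both_maternal_links_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            rt = _read(["S,0,0,h1,y1,HO,1,1,3"])
        assert len(rt) == 0

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            read_records(io.StringIO("sire,score\nS,1\n"))

    def test_phenotyped_sets(self):
        rt = _read(["S1,D,G1,h,y,HO,1,1,1", "S2,0,G1,h,y,HO,1,1,2"])
        assert list(rt.phenotyped_sires()) == ["S1", "S2"]
        assert list(rt.phenotyped_mgs()) == ["G1"]


@pytest.fixture
def toy_ped():
    # G is the sire of dam D; S an unrelated sire
    return build_pedigree(
        ["G", "S", "D"], ["0", "0", "G"], ["0", "0", "0"]
    )


class TestBuildDesign:
    def test_maternal_column_is_mgs_under_smgs(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1"])
        d = build_design(rt, toy_ped, "smgs")
        assert d.z_s[0, toy_ped.index_of(["S"])[0]] == 1
        assert d.z_m[0, toy_ped.index_of(["G"])[0]] == 1

    def test_maternal_column_is_dam_under_smat(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1"])
        d = build_design(rt, toy_ped, "smat")
        assert d.z_m[0, toy_ped.index_of(["D"])[0]] == 1

    def test_designs_differ_only_in_maternal_map(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1", "S,D,G,h2,y1,BS,2,2,2"])
        d1 = build_design(rt, toy_ped, "smgs")
        d2 = build_design(rt, toy_ped, "smat")
        assert (d1.x - d2.x).nnz == 0
        assert (d1.z_hys - d2.z_hys).nnz == 0
        assert (d1.z_s - d2.z_s).nnz == 0
        assert (d1.z_m - d2.z_m).nnz != 0

    def test_shared_hys_column(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1", "S,D,G,h1,y1,HO,1,1,2"])
        d = build_design(rt, toy_ped, "smgs")
        assert d.z_hys.shape[1] == 1
        assert d.z_hys.sum() == 2

    def test_one_nonzero_per_row_per_incidence(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1", "S,D,G,h2,y2,BS,2,1,4"])
        d = build_design(rt, toy_ped, "smgs")
        for z in (d.z_hys, d.z_s, d.z_m):
            assert (z.sum(axis=1) == 1).all()

    def test_pedigree_mgs_overrides_record_mgs(self, toy_ped, caplog):
        rt = _read(["S,D,WRONG,h1,y1,HO,1,1,1"])
        with caplog.at_level("WARNING", logger="calvease.model"):
            d = build_design(rt, toy_ped, "smgs")
        assert d.z_m[0, toy_ped.index_of(["G"])[0]] == 1
        assert "disagreed" in caplog.text

    def test_unresolvable_sire_dropped(self, toy_ped):
        rt = _read(["NOPE,D,G,h1,y1,HO,1,1,1", "S,D,G,h1,y1,HO,1,1,1"])
        with pytest.warns(UserWarning, match="dropped 1"):
            d = build_design(rt, toy_ped, "smgs")
        assert d.n_records == 1


class TestReparameterization:
    def test_reproduces_published_dam_scale_estimates(self):
        vc, t = reparameterize_smgs_to_smat(SMGS_COMPONENTS, SMGS_THRESHOLDS)
        assert vc.model == "smat"
        assert vc.sigma2_s == pytest.approx(0.0239, abs=5e-4)
        assert vc.cov_sm == pytest.approx(0.0242, abs=5e-4)
        assert vc.sigma2_m == pytest.approx(0.0961, abs=5e-4)
        assert vc.sigma2_hys == pytest.approx(0.232, abs=1e-3)
        assert t.cuts[0] == pytest.approx(-1.22, abs=0.01)
        assert t.cuts[1] == pytest.approx(-0.67, abs=0.01)
        assert t.cuts[2] == 0.0

    def test_zero_mgs_variance_is_identity_scale(self):
        vc_in = VarianceComponents(
            model="smgs", sigma2_s=0.02, cov_sm=0.0, sigma2_m=0.0, sigma2_hys=0.2
        )
        t_in = Thresholds([-1.0, 0.0])
        vc, t = reparameterize_smgs_to_smat(vc_in, t_in)
        assert vc.sigma2_m == 0.0
        assert vc.sigma2_s == pytest.approx(0.02)
        assert t.cuts == pytest.approx(t_in.cuts)

    def test_round_trip_scale_identity(self):
        vc, _ = reparameterize_smgs_to_smat(SMGS_COMPONENTS, SMGS_THRESHOLDS)
        c = 1.0 / (1.0 - 3.0 * SMGS_COMPONENTS.sigma2_m)
        dam_scale = np.array(
            [
                [SMGS_COMPONENTS.sigma2_s, 2 * SMGS_COMPONENTS.cov_sm],
                [2 * SMGS_COMPONENTS.cov_sm, 4 * SMGS_COMPONENTS.sigma2_m],
            ]
        )
        assert vc.g0 / c == pytest.approx(dam_scale, abs=1e-15)

    def test_excessive_mgs_variance_rejected(self):
        vc_in = VarianceComponents(
            model="smgs", sigma2_s=0.5, cov_sm=0.0, sigma2_m=0.4, sigma2_hys=0.1
        )
        with pytest.raises(ValueError, match="renormalize"):
            reparameterize_smgs_to_smat(vc_in, Thresholds([0.0]))

    def test_requires_smgs_input(self):
        vc, _ = reparameterize_smgs_to_smat(SMGS_COMPONENTS, SMGS_THRESHOLDS)
        with pytest.raises(ValueError, match="smgs"):
            reparameterize_smgs_to_smat(vc, SMGS_THRESHOLDS)


class TestAssembleMME:
    def _toy(self, toy_ped):
        rt = _read(["S,D,G,h1,y1,HO,1,1,1"])
        design = build_design(rt, toy_ped, "smgs")
        return design

    def test_dimension_and_symmetry(self, toy_ped):
        design = self._toy(toy_ped)
        sys_ = assemble_mme(design, SMGS_COMPONENTS)
        # 3 fixed (one level per factor) + 1 hys + 2*3 genetic
        assert sys_.n_equations == 3 + 1 + 6
        c = sys_.coefficient(np.array([1.0]))
        assert abs(c - c.T).max() == 0

    def test_matches_dense_hand_assembly(self, toy_ped):
        design = self._toy(toy_ped)
        sys_ = assemble_mme(design, SMGS_COMPONENTS)
        t_dense = design.t_matrix().toarray()
        ainv = a_inverse(toy_ped).toarray()
        lam = np.zeros((10, 10))
        lam[3, 3] = 1.0 / SMGS_COMPONENTS.sigma2_hys
        lam[4:, 4:] = np.kron(linalg.inv(SMGS_COMPONENTS.g0), ainv)
        w = np.array([0.7])
        oracle = t_dense.T * w @ t_dense + lam
        assert sys_.coefficient(w).toarray() == pytest.approx(oracle, abs=1e-10)

    def test_unit_weights_reduce_to_normal_equations_plus_precision(self, toy_ped):
        design = self._toy(toy_ped)
        sys_ = assemble_mme(design, SMGS_COMPONENTS)
        t_dense = design.t_matrix().toarray()
        c0 = sys_.coefficient(None).toarray() - sys_.lam.toarray()
        assert c0 == pytest.approx(t_dense.T @ t_dense, abs=1e-12)

    def test_kronecker_blockwise_correctness(self, toy_ped):
        design = self._toy(toy_ped)
        sys_ = assemble_mme(design, SMGS_COMPONENTS)
        ainv = a_inverse(toy_ped).toarray()
        kron = np.kron(SMGS_COMPONENTS.g0_inv, ainv)
        assert sys_.lam.toarray()[4:, 4:] == pytest.approx(kron, abs=1e-10)

    def test_model_tag_mismatch_rejected(self, toy_ped):
        design = self._toy(toy_ped)
        vc_smat, _ = reparameterize_smgs_to_smat(SMGS_COMPONENTS, SMGS_THRESHOLDS)
        with pytest.raises(ValueError, match="tagged"):
            assemble_mme(design, vc_smat)

    def test_rhs_applies_weights(self, toy_ped):
        design = self._toy(toy_ped)
        sys_ = assemble_mme(design, SMGS_COMPONENTS)
        y = np.array([2.0])
        w = np.array([0.5])
        t_dense = design.t_matrix().toarray()
        assert sys_.rhs(y, w) == pytest.approx(t_dense.T @ (w * y))
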