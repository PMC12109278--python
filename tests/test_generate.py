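"""Synthetic-conformation generator: prescribed topology is recovered by
the measurement pipeline, construction is deterministic, and infeasible
prescriptions fail loudly."""

import numpy as np
import pytest

from ritopo import (ConstructionError, GeneratorConfig, PrescribedPartition,
                    decompose_ri, early_invivo_config, late_invivo_config,
                    linking_number, make_relaxed_circle, make_ri,
                    make_supercoiled_circle, writhe)


class TestRelaxedCircle:
    def test_lk_is_rounded_helical_turns(self):
        d = make_relaxed_circle(2100)
        lk = linking_number(d.strandA.points, d.strandB.points)
        assert lk == pytest.approx(200.0, abs=0.01)
        d2 = make_relaxed_circle(2000)
        lk2 = linking_number(d2.strandA.points, d2.strandB.points)
        assert lk2 == pytest.approx(190.0, abs=0.01)  # round(190.476)

    def test_axis_is_planar(self, relaxed_210):
        assert writhe(relaxed_210.axis_points) == pytest.approx(0.0, abs=0.01)

    def test_too_small_rejected(self):
        with pytest.raises(ConstructionError):
            make_relaxed_circle(40)


class TestSupercoiledCircle:
    def test_delta_lk_exact(self, supercoiled_2000):
        lk = linking_number(supercoiled_2000.strandA.points,
                            supercoiled_2000.strandB.points)
        assert lk - 190 == pytest.approx(-10.0, abs=0.2)

    def test_chirality_follows_sign(self):
        neg = make_supercoiled_circle(1200, -6, 1, seed=4)
        pos = make_supercoiled_circle(1200, 6, 1, seed=4)
        assert writhe(neg.axis_points) < -2      # right-handed interwinding
        assert writhe(pos.axis_points) > 2       # left-handed interwinding

    def test_zero_stress_reduces_to_relaxed(self):
        d = make_supercoiled_circle(2000, 0, 1, seed=1)
        lk = linking_number(d.strandA.points, d.strandB.points)
        assert lk - 190 == pytest.approx(0.0, abs=0.05)
        assert writhe(d.axis_points) == pytest.approx(0.0, abs=0.05)


class TestReplicationIntermediates:
    def test_early_in_vivo_partition(self, early_ri):
        dec = decompose_ri(early_ri)
        assert dec.q_unrep == pytest.approx(-12.0, abs=0.3)
        assert dec.q_rep == pytest.approx(2.0, abs=0.3)
        assert dec.q_wrap == pytest.approx(0.0, abs=0.3)
        assert dec.delta_lk_total == pytest.approx(-10.0, abs=0.3)

    def test_late_in_vivo_partition(self, late_ri):
        dec = decompose_ri(late_ri)
        assert dec.q_unrep == pytest.approx(-2.0, abs=0.3)
        assert dec.q_rep == pytest.approx(12.0, abs=0.3)
        assert dec.delta_lk_total == pytest.approx(10.0, abs=0.3)

    def test_zero_partition_is_torsionally_relaxed(self):
        cfg = GeneratorConfig(n_bp=2000, frac_replicated=509 / 2000, seed=2)
        dec = decompose_ri(make_ri(cfg))
        for comp in dec.components:
            assert comp == pytest.approx(0.0, abs=0.3)
        assert dec.delta_lk_total == pytest.approx(0.0, abs=0.1)

    def test_component_recovery_other_partition(self):
        cfg = GeneratorConfig(
            n_bp=2000, frac_replicated=509 / 2000, seed=5,
            prescribed_partition=PrescribedPartition(
                q_unrep=-6.0, q_wrap=0.0, q_rep=-2.0,
                precatenane_Ca=-2.0, braid_writhe=0.0))
        dec = decompose_ri(make_ri(cfg))
        assert dec.q_unrep == pytest.approx(-6.0, abs=0.3)
        assert dec.q_rep == pytest.approx(-2.0, abs=0.3)
        assert dec.c4_precatenanes == pytest.approx(-2.0, abs=0.3)
        assert dec.c5_plectonemes_of_precatenanes == pytest.approx(0.0, abs=0.3)

    def test_five_components_sum_to_total(self, early_ri):
        dec = decompose_ri(early_ri)
        assert dec.components.sum() == pytest.approx(dec.delta_lk_total,
                                                     abs=1e-6)
        assert dec.c1_dTw_unrep + dec.c2_Wr_unrep == pytest.approx(
            dec.q_unrep, abs=1e-6)
        assert (dec.c4_precatenanes
                + dec.c5_plectonemes_of_precatenanes) == pytest.approx(
            dec.q_rep, abs=1e-6)

    def test_total_lk_is_integer(self, early_ri):
        lk = linking_number(early_ri.parentalA.points,
                            early_ri.parentalB.points)
        assert lk == pytest.approx(round(lk), abs=1e-3)
        assert round(lk) == 132  # 1491/10.5 - 10

    def test_wrap_prescription_rejected(self):
        cfg = GeneratorConfig(
            n_bp=2000, frac_replicated=509 / 2000,
            prescribed_partition=PrescribedPartition(
                q_unrep=-8.0, q_wrap=-2.0, q_rep=0.0))
        with pytest.raises(ConstructionError):
            make_ri(cfg)


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg_a = early_invivo_config(seed=7)
        cfg_b = early_invivo_config(seed=7)
        ra, rb = make_ri(cfg_a), make_ri(cfg_b)
        assert np.array_equal(ra.parentalA.points, rb.parentalA.points)
        assert np.array_equal(ra.daughter_new2.points, rb.daughter_new2.points)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = late_invivo_config(seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back == cfg

    def test_partition_consistency_enforced(self):
        with pytest.raises(ValueError):
            PrescribedPartition(q_rep=2.0, precatenane_Ca=1.0,
                                braid_writhe=0.5)
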