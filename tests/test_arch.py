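"""Architecture construction, merge rules, forward shapes and counting."""

import numpy as np
import pytest

import plnet.nn as nn
from plnet import ArchConfig, build_plnet, count_parameters, scale_channels
from plnet.arch import save_checkpoint, load_checkpoint


class TestScaleChannels:
    @pytest.mark.parametrize(
        "ocs,expected",
        [
            (1.0, [32, 64, 128, 256, 512]),
            (0.5, [16, 32, 64, 128, 256]),
            (0.75, [24, 48, 96, 192, 384]),
        ],
    )
    def test_examples(self, ocs, expected):
        assert scale_channels([32, 64, 128, 256, 512], ocs) == expected

    def test_clamps_to_one_and_rejects_nonpositive(self):
        assert scale_channels([1, 2], 0.01) == [1, 1]
        with pytest.raises(ValueError):
            scale_channels([32], 0.0)
        with pytest.raises(ValueError):
            scale_channels([32], -1.0)

    def test_monotone_in_ocs(self):
        base = [32, 64, 128, 256, 512]
        prev = scale_channels(base, 0.1)
        for ocs in np.linspace(0.2, 2.0, 19):
            cur = scale_channels(base, ocs)
            assert all(c >= p for c, p in zip(cur, prev))
            prev = cur


class TestConfigValidation:
    def test_rejects_indivisible_input_size(self):
        with pytest.raises(ValueError):
            ArchConfig(input_size=100)

    def test_rejects_too_many_stages(self):
        with pytest.raises(ValueError):
            ArchConfig(base_channels=(8, 16), n_stages=2)

    def test_stage_membership_matches_depth_plan(self):
        cfg = ArchConfig()
        model = build_plnet(cfg, seed=0)
        plan = model.level_plan()
        # stage 1 reaches 28^2, stage 2 alone owns the 14^2 bottleneck
        assert [row["stage_membership"] for row in plan] == [
            [1, 2], [1, 2], [1, 2], [1, 2], [2]
        ]
        assert [row["spatial_size"] for row in plan] == [224, 112, 56, 28, 14]


class TestParameterCounting:
    def test_conv_unit_hand_count(self):
        unit = nn.ConvUnit(3, 2, np.random.default_rng(0))
        n = sum(p.data.size for p in unit.parameters())
        assert n == 9 * 3 * 2 + 2 + 2 * 2  # kernel + bias + norm scale/shift

    def test_count_independent_of_input_size(self):
        a = count_parameters(build_plnet(ArchConfig(input_size=224)))
        b = count_parameters(build_plnet(ArchConfig(input_size=448)))
        assert a == b

    def test_step_increment_is_exactly_affine(self):
        counts = {
            n: count_parameters(build_plnet(ArchConfig(n_steps=n)))
            for n in (1, 2, 3)
        }
        assert counts[3] - counts[2] == counts[2] - counts[1]

    def test_ocs_scaling_is_nearly_quadratic(self):
        full = count_parameters(build_plnet(ArchConfig()))
        half = count_parameters(build_plnet(ArchConfig(ocs=0.5)))
        assert 0.24 <= half / full <= 0.27

    def test_stage1_parameters_strict_subset(self):
        model = build_plnet(ArchConfig())
        s1 = {id(p) for p in model.stage_parameters(1)}
        s2 = {id(p) for p in model.stage_parameters(2)}
        assert s1 < s2
        assert s2 == {id(p) for p in model.parameters()}

    def test_single_stage_depth4_is_smaller(self):
        small = count_parameters(
            build_plnet(
                ArchConfig(base_channels=(32, 64, 128, 256), n_stages=1)
            )
        )
        assert small < count_parameters(build_plnet(ArchConfig()))


class TestMergeRules:
    def test_fsc_merge_matches_hand_composition(self, tiny_model, rng):
        """concat -> conv -> norm -> ReLU composed manually equals fsc_merge."""
        c = tiny_model.channels
        x = nn.Tensor(rng.normal(size=(1, c[0], 16, 16)))
        xh = nn.Tensor(rng.normal(size=(1, c[1], 16, 16)))
        got = tiny_model.fsc_merge(x, xh, step=1, level=0)
        unit = tiny_model.dec[0][1]
        manual = nn.relu(unit.bn(unit.conv(nn.concat([x, xh])), False))
        np.testing.assert_array_equal(got.data, manual.data)

    def test_fsc_merge_output_width_is_level_width(self, tiny_model, rng):
        c = tiny_model.channels
        x = nn.Tensor(rng.normal(size=(1, c[1], 8, 8)))
        xh = nn.Tensor(rng.normal(size=(1, c[2], 8, 8)))
        assert tiny_model.fsc_merge(x, xh, 0, level=1).shape[1] == c[1]

    def test_fsc_merge_rejects_spatial_mismatch(self, tiny_model, rng):
        c = tiny_model.channels
        x = nn.Tensor(rng.normal(size=(1, c[0], 16, 16)))
        xh = nn.Tensor(rng.normal(size=(1, c[1], 8, 8)))
        with pytest.raises(ValueError):
            tiny_model.fsc_merge(x, xh, 0, 0)

    def test_bsc_merge_matches_hand_composition(self, tiny_model, rng):
        c = tiny_model.channels
        x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)))
        prev = nn.Tensor(rng.normal(size=(1, c[0], 8, 8)))
        got = tiny_model.bsc_merge(x, prev, step=1, level=0)
        unit = tiny_model.enc[0][1]
        manual = nn.relu(unit.bn(unit.conv(nn.concat([x, prev])), False))
        np.testing.assert_array_equal(got.data, manual.data)

    def test_bsc_merge_requires_backward_feature_after_first_pass(
        self, tiny_model, rng
    ):
        x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)))
        with pytest.raises(ValueError):
            tiny_model.bsc_merge(x, None, step=1, level=0)

    def test_bsc_merge_without_backward_feature_ignores_slot(self, tiny_model, rng):
        """First traversal: the zero-filled backward slot must contribute
        nothing beyond the conv response to x itself."""
        c = tiny_model.channels
        x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)))
        zeros = nn.Tensor(np.zeros((1, c[0], 8, 8)))
        a = tiny_model.bsc_merge(x, None, step=0, level=0)
        b = tiny_model.bsc_merge(x, zeros, step=0, level=0)
        np.testing.assert_array_equal(a.data, b.data)


class TestForward:
    def test_output_shape_matches_input_for_every_stage(self, tiny_model):
        x = np.zeros((2, 3, 32, 32))
        outs = tiny_model.forward_all(x)
        assert len(outs.preacts) == 2
        for p in outs.preacts:
            assert p.shape == (2, 1, 32, 32)

    def test_rejects_bad_spatial_size(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward_all(np.zeros((1, 3, 30, 30)))

    def test_rejects_stage_out_of_range(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.ipl_forward(np.zeros((1, 3, 32, 32)), stage=3)

    def test_single_step_is_plain_encode_decode(self, rng):
        """n_steps=1 degenerates to one vanilla U-shaped traversal."""
        cfg = ArchConfig(
            base_channels=(4, 8, 16), input_size=16, n_steps=1, n_stages=1
        )
        model = build_plnet(cfg, seed=5)
        x = nn.Tensor(rng.normal(size=(1, 3, 16, 16)))
        # hand-unrolled single pass over the same blocks
        e0 = model.bsc_merge(x, None, 0, 0)
        e1 = model.bsc_merge(nn.maxpool2x2(e0), None, 0, 1)
        top = model.bridge(model.enc[2][0](nn.maxpool2x2(e1), False), False)
        d1 = model.fsc_merge(e1, model.ups[1](top, False), 0, 1)
        d0 = model.fsc_merge(e0, model.ups[0](d1, False), 0, 0)
        manual = model.heads[0](d0)
        got = model.ipl_forward(x, stage=1)
        np.testing.assert_array_equal(got.data, manual.data)

    def test_two_step_forward_equals_unrolled_composition(self, tiny_model, rng):
        """ipl_forward with two steps bit-matches the explicitly unrolled
        two-pass computation written without the recursion abstraction."""
        m = tiny_model
        x = nn.Tensor(rng.normal(size=(1, 3, 32, 32)))

        def one_pass(step, bottleneck, back):
            enc = {}
            cur = x
            for lvl in range(bottleneck + 1):
                inp = cur if lvl == 0 else nn.maxpool2x2(enc[lvl - 1])
                if lvl < m.config.depth - 1:
                    enc[lvl] = m.bsc_merge(inp, back.get(lvl), step, lvl)
                else:
                    enc[lvl] = m.enc[lvl][step](inp, False)
            top = enc[bottleneck]
            if bottleneck == m.config.depth - 1:
                top = m.bridge(top, False)
            u, dec = top, {}
            for lvl in range(bottleneck - 1, -1, -1):
                u = m.fsc_merge(enc[lvl], m.ups[lvl](u, False), step, lvl)
                dec[lvl] = u
            back_out = dict(dec)
            if bottleneck < m.config.depth - 1:
                back_out[bottleneck] = enc[bottleneck]
            return dec[0], back_out

        # stage 1 (bottleneck level 1), then stage 2 (level 2)
        _, back = one_pass(0, 1, {})
        d0, back = one_pass(1, 1, back)
        _, back = one_pass(0, 2, back)
        d0, _ = one_pass(1, 2, back)
        manual = m.heads[1](d0)
        got = m.ipl_forward(x, stage=2)
        np.testing.assert_array_equal(got.data, manual.data)


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    x = rng.normal(size=(1, 3, 32, 32))
    before = tiny_model.forward_all(x).preacts[-1].data
    save_checkpoint(tiny_model, tmp_path / "ckpt.npz")
    loaded = load_checkpoint(tmp_path / "ckpt.npz")
    after = loaded.forward_all(x).preacts[-1].data
    np.testing.assert_array_equal(before, after)
    assert loaded.config == tiny_model.config
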