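"""Circuit construction: counts, connectivity rules, weights, delays, symmetry."""

import numpy as np
import pytest

import coilswim as cs
from coilswim.circuits import (
    GAP,
    GLUT,
    GLY,
    compute_delay,
    euclidean_distance,
    load_params,
)


def _kind_of(model):
    """Map each global neuron index to its (kind, side)."""
    table = {}
    start = 0
    for p in model.populations:
        for i in range(p.count):
            table[start + i] = (p.kind, p.side, i)
        start += p.count
    return table


class TestGeometry:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((0.0, 1.0, 1.6, 1.0), None, 1.6),  # ipsilateral neighbors
            ((0.0, 1.0, 0.0, -1.0), None, 2.0),  # contralateral same somite
            ((0.0, 1.0, 1.6, -1.0), None, 2.561),  # contralateral adjacent
        ],
    )
    def test_euclidean_distance(self, p1, p2, expected):
        x1, y1, x2, y2 = p1
        assert euclidean_distance(x1, y1, x2, y2) == pytest.approx(expected, abs=1e-3)

    def test_delay_examples(self):
        assert compute_delay(1.6, 0.8) == pytest.approx(2.0)
        assert compute_delay(2.561, 0.8) == pytest.approx(3.2, abs=0.01)
        assert compute_delay(0.0, 4.0) == 0.0
        with pytest.raises(ValueError):
            compute_delay(1.0, 0.0)

    def test_swimming_intersegmental_delays_in_reported_range(self, beat_glide_model):
        # one- and two-segment chemical projections land in the 2-6.5 ms band
        delays = [
            c.delay for c in beat_glide_model.connections if c.kind != GAP
        ]
        assert 2.0 <= np.median(delays) <= 6.5


class TestPopulationsAndCounts:
    def test_single_coiling_has_50_neurons(self, single_model):
        assert single_model.n_neurons == 50

    def test_double_coiling_has_90_neurons(self, double_model):
        assert double_model.n_neurons == 90

    def test_beat_glide_has_150_neurons(self, beat_glide_model):
        assert beat_glide_model.n_neurons == 150

    def test_unsupported_body_sizes_rejected(self):
        with pytest.raises(ValueError):
            cs.build_single_coiling(n_somites=12)
        with pytest.raises(ValueError):
            cs.build_beat_and_glide("base", n_somites=20)
        with pytest.raises(ValueError):
            cs.build_beat_and_glide("no_such_variant")

    def test_30_somite_variants_build(self):
        m = cs.build_single_coiling(n_somites=30)
        assert m.pop_slice("MN", "left").stop - m.pop_slice("MN", "left").start == 30
        # IC axons extend to all somites in the large model
        kinds = _kind_of(m)
        mn_left = m.pop_slice("MN", "left")
        ic_left = m.pop_slice("IC", "left")
        coupled = {
            c.post
            for c in m.connections
            if c.kind == GAP and ic_left.start <= c.pre < ic_left.stop
            and mn_left.start <= c.post < mn_left.stop
        }
        assert len(coupled) == 30


class TestConnectivityRules:
    def test_mid_chain_mn_gap_neighborhood(self, single_model):
        kinds = _kind_of(single_model)
        mn_left = single_model.pop_slice("MN", "left")
        mid = mn_left.start + 5  # somite 6
        partners = [
            kinds[c.post]
            for c in single_model.connections
            if c.kind == GAP and c.pre == mid
        ]
        mn_partners = [p for p in partners if p[0] == "MN"]
        v0d_partners = [p for p in partners if p[0] == "V0d"]
        assert len(mn_partners) == 6  # three rostral + three caudal
        assert len(v0d_partners) == 6  # cross-chain, same-somite excluded

    def test_first_v0d_glycine_targets_clip_at_rostral_boundary(self, single_model):
        kinds = _kind_of(single_model)
        v0d1 = single_model.pop_slice("V0d", "left").start  # somite 1
        mn_targets = sorted(
            kinds[c.post][2]
            for c in single_model.connections
            if c.kind == GLY and c.pre == v0d1 and kinds[c.post][0] == "MN"
        )
        assert mn_targets == [0, 1, 2, 3, 4, 5]  # somites 1..6 only
        sides = {
            kinds[c.post][1]
            for c in single_model.connections
            if c.kind == GLY and c.pre == v0d1
        }
        assert sides == {"right"}

    def test_no_ipsilateral_glycine_in_coiling_models(
        self, single_model, double_model
    ):
        for model in (single_model, double_model):
            kinds = _kind_of(model)
            for c in model.connections:
                if c.kind == GLY:
                    assert kinds[c.pre][1] != kinds[c.post][1]

    def test_v2a_to_mn_absent_in_double_coiling(self, double_model):
        kinds = _kind_of(double_model)
        for c in double_model.connections:
            if c.kind != GAP and kinds[c.pre][0] == "V2a":
                assert kinds[c.post][0] != "MN"

    def test_v2a_descending_targets_clip_at_caudal_boundary(self, beat_glide_model):
        kinds = _kind_of(beat_glide_model)
        v2a = beat_glide_model.pop_slice("V2a", "left")
        v2a10 = v2a.start + 9  # segment 10
        v2a_targets = sorted(
            kinds[c.post][2] + 1
            for c in beat_glide_model.connections
            if c.kind == GLUT and c.pre == v2a10 and kinds[c.post][0] == "V2a"
        )
        assert v2a_targets == [11, 12, 13, 14, 15]  # i+1..i+6 clipped at 15

    def test_all_projection_targets_exist(self, beat_glide_model):
        n = beat_glide_model.n_neurons + 2 * beat_glide_model.n_muscle_cells
        for c in beat_glide_model.connections + beat_glide_model.muscle_synapses:
            assert 0 <= c.pre < beat_glide_model.n_neurons
            assert 0 <= c.post < n


class TestWeightsAndDelays:
    @pytest.mark.parametrize(
        "factory, sheet_name, kwargs",
        [
            (cs.build_single_coiling, "single_coiling", {}),
            (cs.build_double_coiling, "double_coiling", {}),
            (cs.build_beat_and_glide, "beat_glide_base", {"variant": "base"}),
        ],
    )
    def test_every_weight_matches_its_table_cell(self, factory, sheet_name, kwargs):
        # disable the dI6 weight noise so the lookup is exact
        overrides = (
            {"chem_rules.di6_noise_sd": 0.0} if "beat" in sheet_name else None
        )
        model = factory(overrides=overrides, **kwargs)
        sheet = load_params(sheet_name)
        kinds = _kind_of(model)
        gap_w = {
            tuple(sorted(key.split("_"))): w
            for key, w in sheet["gap_weights"].items()
        }
        chem_w = {tuple(k.split("_")): w for k, w in sheet["chem_weights"].items()}
        for c in model.connections:
            pre_kind, post_kind = kinds[c.pre][0], kinds[c.post][0]
            if c.kind == GAP:
                expected = gap_w[tuple(sorted((pre_kind, post_kind)))]
            else:
                expected = chem_w[(pre_kind, post_kind)]
            assert c.weight == pytest.approx(expected), (pre_kind, post_kind)
        for c in model.muscle_synapses:
            assert c.weight == pytest.approx(sheet["chem_weights"]["MN_Muscle"])

    def test_every_delay_equals_distance_over_cv(self, double_model):
        x, y = double_model.neuron_positions()
        for c in double_model.connections:
            d = euclidean_distance(x[c.pre], y[c.pre], x[c.post], y[c.post])
            assert c.delay == pytest.approx(d / double_model.cv)

    def test_gap_junctions_built_symmetrically(self, single_model):
        gaps = {
            (c.pre, c.post): c.weight
            for c in single_model.connections
            if c.kind == GAP
        }
        for (pre, post), w in gaps.items():
            assert gaps.get((post, pre)) == w

    def test_mirror_symmetry_of_connection_sets(self, single_model):
        m = single_model
        kinds = _kind_of(m)

        def signature(conns):
            flip = {"left": "right", "right": "left"}
            out = []
            for c in conns:
                k1, s1, i1 = kinds[c.pre]
                k2, s2, i2 = kinds[c.post]
                out.append((k1, flip[s1], i1, k2, flip[s2], i2, c.kind,
                            round(c.weight, 9), round(c.delay, 9)))
            return sorted(out)

        original = sorted(
            (kinds[c.pre] + kinds[c.post] + (c.kind, round(c.weight, 9),
                                             round(c.delay, 9)))
            for c in m.connections
        )
        reflected = sorted(
            tuple(x) for x in (tuple(s) for s in signature(m.connections))
        )
        assert original == reflected

    def test_glycinergic_reversal_follows_developmental_stage(
        self, single_model, double_model, beat_glide_model
    ):
        assert single_model.e_gly == -45.0
        assert double_model.e_gly == -58.0
        assert beat_glide_model.e_gly == -70.0

    def test_unknown_override_path_rejected(self):
        with pytest.raises(KeyError):
            cs.build_single_coiling(overrides={"synapse.no_such_key": 1.0})


class TestExports:
    def test_connectome_export_roundtrip(self, single_model):
        frame = cs.export_connectome(single_model)
        assert set(frame.columns) == {"pre", "post", "kind", "weight", "delay"}
        assert len(frame) == len(single_model.connections) + len(
            single_model.muscle_synapses
        )
        assert (frame["weight"] >= 0).all()
        assert (frame["delay"] >= 0).all()
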