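import math
from collections import defaultdict

import numpy as np
import pytest

from aiiconn import (
    CellType,
    Compartment,
    Direction,
    SynKind,
    build_synapse_table,
    aggregate_summary,
    convergence,
    dyad_composition,
    tally_inputs,
    tally_outputs,
)
from aiiconn.connectome import (
    PairingConfig,
    PairingConflictError,
    SynapseRecord,
    assign_compartment,
    percent_display,
    read_synapse_tsv,
    round_half_up,
    write_synapse_tsv,
)
from aiiconn.skeleton_io import SkeletonForest, VoxelScale
from aiiconn.synthetic_data import (
    SynthParams,
    dyad_fixture,
    generate,
    soma_basket_fixture,
    aii_inputs_fixture,
    axon_outputs_fixture,
    focal_cell_fixture,
)

from conftest import make_skeleton, truth_types


def rec(i, pre, post, kind=SynKind.CONVENTIONAL, pre_t=CellType.AC, post_t=CellType.AII,
        comp=Compartment.UNASSIGNED, pos=(0.0, 0.0, 0.0), dyad_site=None):
    return SynapseRecord(
        synapse_id=i, pre_id=pre, pre_type=pre_t, post_id=post, post_type=post_t,
        kind=kind, position=pos, compartment=comp, dyad_site=dyad_site,
    )


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(2.5, 3), (2.49, 2), (0.5, 1), (88.7, 89)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    @pytest.mark.parametrize(
        "fraction,text",
        [(0.85, "85"), (0.635, "63.5"), (0.095, "9.5"), (1212 / 1425, "85.1"),
         (0.5, "50"), (1.0, "100")],
    )
    def test_percent_display(self, fraction, text):
        assert percent_display(fraction) == text


class TestBuildSynapseTable:
    def _forest(self, comments_a, comments_b, pos_a=None, pos_b=None):
        pos_a = pos_a or {1: (0, 0, 0), 2: (10, 0, 0)}
        pos_b = pos_b or {11: (0, 0, 1), 12: (10, 0, 1)}
        ska = make_skeleton(3, pos_a, [(1, 2)], comments=comments_a)
        skb = make_skeleton(7, pos_b, [(11, 12)], comments=comments_b)
        forest = SkeletonForest(scale=VoxelScale(1, 1, 1), skeletons={3: ska, 7: skb})
        from aiiconn.skeleton_io import extract_annotations

        extract_annotations(forest)
        return forest

    TYPES = {3: CellType.AC, 7: CellType.AII}

    def test_id_matched_pair(self):
        forest = self._forest({2: "syn:conv:out:AII:7"}, {12: "syn:conv:in:AC:3"})
        records = build_synapse_table(forest, None, self.TYPES)
        assert len(records) == 1
        r = records[0]
        assert (r.pre_id, r.post_id, r.kind) == (3, 7, SynKind.CONVENTIONAL)
        assert r.provenance == "paired:id"

    def test_one_sided_pre_only(self):
        forest = self._forest({2: "syn:conv:out:AII"}, {})
        records = build_synapse_table(forest, None, self.TYPES)
        assert len(records) == 1
        assert records[0].provenance == "pre-only"
        assert records[0].post_id is None
        assert records[0].post_type is CellType.AII  # from the annotation

    def test_proximity_pairing(self):
        forest = self._forest({2: "syn:conv:out:AII"}, {12: "syn:conv:in:AC"})
        records = build_synapse_table(forest, None, self.TYPES)
        assert len(records) == 1
        assert records[0].provenance == "paired:proximity"

    def test_proximity_outside_epsilon(self):
        forest = self._forest(
            {2: "syn:conv:out:AII"}, {12: "syn:conv:in:AC"},
            pos_b={11: (0, 5000, 0), 12: (10, 5000, 0)},
        )
        records = build_synapse_table(forest, None, self.TYPES)
        assert {r.provenance for r in records} == {"pre-only", "post-only"}

    def test_kind_conflict_raises(self):
        forest = self._forest({2: "syn:ribbon:out:AII:7"}, {12: "syn:conv:in:AC:3"})
        with pytest.raises(PairingConflictError):
            build_synapse_table(forest, None, {3: CellType.RB, 7: CellType.AII})

    def test_ribbon_from_nonbipolar_flagged(self):
        forest = self._forest({2: "syn:ribbon:out:AII:7"}, {12: "syn:ribbon:in:AC:3"})
        records = build_synapse_table(forest, None, self.TYPES)  # pre is AC
        assert records[0].flags == ("ribbon-from-nonbipolar",)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pairing_recovery_on_generator(self, seed):
        # no partner ids in comments: proximity pairing must recover truth
        params = SynthParams(
            seed=seed, annotate_partner_ids=False, n_output_synapses=200,
            n_dyads=0, ribbons_per_aii_mean=40,
        )
        forest, truth = generate(params)
        types = truth_types(truth)
        records = build_synapse_table(forest, None, types)
        recovered = {
            (r.pre_id, r.pre_node, r.post_id, r.post_node)
            for r in records if r.provenance.startswith("paired")
        }
        true_pairs = set(map(tuple, truth.pairs))
        frac = len(recovered & true_pairs) / len(true_pairs)
        assert frac >= 0.99

    def test_conservation_two_sided(self, default_volume, default_frame, default_types):
        _, forest, truth = default_volume
        records = build_synapse_table(forest, default_frame, default_types)
        assert all(r.provenance.startswith("paired") for r in records)
        outputs = defaultdict(int)
        inputs = defaultdict(int)
        for r in records:
            outputs[(r.pre_id, r.post_id)] += 1
            inputs[(r.post_id, r.pre_id)] += 1
        assert outputs.keys() == {(b, a) for a, b in inputs.keys()}
        for (a, b), n in outputs.items():
            assert inputs[(b, a)] == n


class TestAssignCompartment:
    def test_on_soma_node(self, unit_scale):
        sk = make_skeleton(1, {1: (0, 0, 0), 2: (100, 0, 0)}, [(1, 2)], soma=1)
        assert (
            assign_compartment(math.nan, sk, 1, unit_scale) is Compartment.SOMA
        )

    def test_distal_by_depth(self, unit_scale):
        sk = make_skeleton(1, {1: (0, 0, 0), 2: (50000, 0, 0)}, [(1, 2)], soma=1)
        # 50 µm from soma, depth 1.2
        assert (
            assign_compartment(1.2, sk, 2, unit_scale) is Compartment.DISTAL_DENDRITE
        )

    def test_proximal_by_depth(self, unit_scale):
        sk = make_skeleton(1, {1: (0, 0, 0), 2: (50000, 0, 0)}, [(1, 2)], soma=1)
        assert (
            assign_compartment(0.1, sk, 2, unit_scale) is Compartment.PROXIMAL_DENDRITE
        )

    def test_unassigned_without_info(self):
        assert assign_compartment(math.nan, None, None, None) is Compartment.UNASSIGNED


class TestTallies:
    def test_zero_records(self):
        t = tally_inputs(101, [])
        assert t.total == 0 and t.rows == {}

    def test_aii2_on_layer_percent(self):
        records = aii_inputs_fixture()
        t = tally_inputs(102, records)
        assert t.count("AC") == 177
        assert t.count("AC", "distal_dendrite") == 157
        assert t.percent_int("AC", "distal_dendrite") == 89

    def test_aii3_on_layer_percent(self):
        t = tally_inputs(103, aii_inputs_fixture())
        assert t.count("AC") == 176
        assert t.percent_int("AC", "distal_dendrite") == 91

    def test_rb_input_counts(self):
        records = aii_inputs_fixture()
        assert [tally_inputs(c, records).count("RB") for c in (101, 102, 103)] == [173, 171, 176]

    def test_pooled_axon_outputs(self):
        from aiiconn.synthetic_data import AXON_FIXTURE_IDS

        t = tally_outputs(AXON_FIXTURE_IDS, axon_outputs_fixture())
        assert t.total == 1425
        assert t.count("AII") == 1212
        assert t.percent_int("AII") == 85
        assert t.count("RB") == 173
        assert t.percent_int("RB") == 12
        assert t.count("ON_CB") == 35
        assert t.count("UNIDENTIFIED") == 5

    def test_cell2_outputs(self):
        t = tally_outputs([72], focal_cell_fixture(2))
        assert t.total == 106
        assert t.count("RB") == 18
        assert t.percent_int("RB") == 17
        assert t.percent_int("AII") == 81

    def test_cell2_inputs(self):
        t = tally_inputs(72, focal_cell_fixture(2))
        assert t.total == 297
        assert t.count("AC") == 183

    def test_single_record_full_share(self):
        t = tally_outputs([1], [rec(0, 1, 2)])
        assert t.percent_int("AII") == 100

    def test_subtype_collapses_to_parent(self):
        records = [rec(0, 1, 2, post_t=CellType.ON_CB6), rec(1, 1, 3, post_t=CellType.ON_CB)]
        t = tally_outputs([1], records)
        assert t.count("ON_CB") == 2

    def test_percents_sum_to_100(self):
        t = tally_outputs([72], focal_cell_fixture(2))
        total_pct = sum(
            r.percent_int for k, r in t.rows.items() if k[1] is None
        )
        assert abs(total_pct - 100) <= len(t.rows)

    def test_permutation_invariance(self):
        records = focal_cell_fixture(2)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        t1 = tally_outputs([72], records)
        t2 = tally_outputs([72], shuffled)
        assert {k: r.count for k, r in t1.rows.items()} == {k: r.count for k, r in t2.rows.items()}


class TestAggregateSummary:
    def _tables(self, counts_by_cell):
        tables = []
        for cell, n in counts_by_cell.items():
            records = [rec(i, 1000 + i, cell, kind=SynKind.RIBBON, pre_t=CellType.RB)
                       for i in range(n)]
            tables.append(tally_inputs(cell, records))
        return tables

    def test_rb_row_mean_sd(self):
        out = aggregate_summary(self._tables({1: 173, 2: 171, 3: 176}))
        row = out[("RB", None)]
        assert row.mean_int == 173
        assert row.sd_int == 3
        assert row.mean == pytest.approx(173.333, abs=1e-3)
        assert row.sd == pytest.approx(np.std([173, 171, 176], ddof=1))

    def test_ac_total_row(self):
        out = aggregate_summary(self._tables({1: 178, 2: 177, 3: 176}))
        row = out[("RB", None)]
        assert (row.mean_int, row.sd_int) == (177, 1)

    def test_identical_tables_sd_zero(self):
        out = aggregate_summary(self._tables({1: 50, 2: 50, 3: 50}))
        assert out[("RB", None)].sd == 0.0

    def test_mismatched_keys_error(self):
        t1 = tally_inputs(1, [rec(0, 10, 1, kind=SynKind.RIBBON, pre_t=CellType.RB)])
        t2 = tally_inputs(2, [rec(0, 10, 2, pre_t=CellType.AC)])
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_summary([t1, t2])


class TestConvergence:
    def test_printed_convention(self):
        # 130 synapses from 61 axons onto 3 cells
        records = axon_outputs_fixture()
        from aiiconn.synthetic_data import AII_FIXTURE_IDS, AXON_FIXTURE_IDS

        conv = convergence(AXON_FIXTURE_IDS, AII_FIXTURE_IDS, records)
        assert conv.total_synapses == 130
        assert conv.mean_per_presynaptic == pytest.approx(130 / 61)
        assert round_half_up(conv.mean_per_presynaptic) == 2

    def test_one_each(self):
        records = [rec(i, 10 + i, 20 + i) for i in range(3)]
        conv = convergence([10, 11, 12], [20, 21, 22], records)
        assert conv.mean_per_presynaptic == 1.0
        assert conv.mean_per_connected_pair == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pre = list(range(50))
        post = list(range(100, 150))
        records = [
            rec(i, int(rng.choice(pre)), int(rng.choice(post)))
            for i in range(int(rng.integers(50, 400)))
        ]
        conv = convergence(pre, post, records)
        # oracle: direct pair enumeration
        expected = defaultdict(int)
        for r in records:
            expected[(r.pre_id, r.post_id)] += 1
        assert conv.pair_counts == dict(expected)
        assert conv.total_synapses == len(records)
        assert conv.mean_per_connected_pair == pytest.approx(
            len(records) / len(expected)
        )


class TestDyads:
    def test_printed_mixture(self):
        comp = dyad_composition(range(201, 241), dyad_fixture(100))
        assert comp.dyads == {"AC+AII": 75, "AC+A17": 18, "AC+UNIDENTIFIED": 7}
        assert comp.shares["AC+AII"] == pytest.approx(0.75)
        assert comp.shares["AC+A17"] == pytest.approx(0.18)
        assert comp.shares["AC+UNIDENTIFIED"] == pytest.approx(0.07)

    def test_single_dyad(self):
        records = [
            rec(0, 201, 71, kind=SynKind.RIBBON, pre_t=CellType.RB, post_t=CellType.AC,
                dyad_site=0),
            rec(1, 201, 102, kind=SynKind.RIBBON, pre_t=CellType.RB, post_t=CellType.AII,
                dyad_site=0),
        ]
        comp = dyad_composition([201], records)
        assert comp.shares == {"AC+AII": 1.0}

    def test_triad_flagged_and_excluded(self):
        records = [
            rec(i, 201, 70 + i, kind=SynKind.RIBBON, pre_t=CellType.RB,
                post_t=CellType.AC if i == 0 else CellType.AII, dyad_site=0)
            for i in range(3)
        ]
        comp = dyad_composition([201], records)
        assert comp.triads == 1
        assert comp.dyads == {}

    def test_position_grouping_fallback(self):
        # no dyad_site ids: positions within 300 nm group together
        records = [
            rec(0, 201, 71, kind=SynKind.RIBBON, pre_t=CellType.RB, post_t=CellType.AC,
                pos=(0.0, 0.0, 0.0)),
            rec(1, 201, 102, kind=SynKind.RIBBON, pre_t=CellType.RB, post_t=CellType.AII,
                pos=(100.0, 0.0, 0.0)),
            rec(2, 201, 103, kind=SynKind.RIBBON, pre_t=CellType.RB, post_t=CellType.AII,
                pos=(50000.0, 0.0, 0.0)),
        ]
        comp = dyad_composition([201], records)
        assert comp.dyads == {"AC+AII": 1}
        assert comp.monads == 1


class TestSomaBasket:
    def test_output_fractions(self):
        from aiiconn.synthetic_data import SOMA_NEURITE_IDS

        t = tally_outputs(SOMA_NEURITE_IDS, soma_basket_fixture())
        assert t.total == 113
        assert t.count("AII") == 90
        assert t.percent_int("AII") == 80


class TestTSVRoundTrip:
    def test_round_trip(self, tmp_path):
        records = focal_cell_fixture(1)[:20] + dyad_fixture(5)
        p = tmp_path / "synapses.tsv"
        write_synapse_tsv(records, p)
        again = read_synapse_tsv(p)
        assert len(again) == len(records)
        for a, b in zip(again, records):
            assert (a.pre_id, a.pre_type, a.post_id, a.post_type, a.kind) == (
                b.pre_id, b.pre_type, b.post_id, b.post_type, b.kind
            )
            assert a.compartment == b.compartment
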