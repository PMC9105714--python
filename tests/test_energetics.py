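import numpy as np
import pytest

from mbgag.contact_analysis import contact_fractions
from mbgag.energetics import (
    EnergyComponents,
    additivity_check,
    aggregate_components,
    filter_frames,
    per_drug_normalize,
    read_components_tsv,
    reproduce_reference_table,
    surrogate_energy,
)
from mbgag.gag_models import build_gag
from mbgag.reference_tables import ENERGY_TABLE
from mbgag.synthetic_traj import MBState, Scenario, generate_scripted


def _blocks_scenario(counts, frames_per_block=3):
    """Scripted trajectory whose per-frame bound count walks the blocks."""
    def script(frame):
        count = counts[frame // frames_per_block]
        return [MBState(bound=i < count) for i in range(10)]

    n = len(counts) * frames_per_block
    return Scenario(n_frames=n, mb_count=10, gag_preset="HP", script=script)


class TestFilterFrames:
    def test_retains_blocks_meeting_threshold(self):
        traj, _ = generate_scripted(_blocks_scenario([2, 3, 5]))
        res = filter_frames(traj, build_gag("HP"), min_bound=3)
        assert list(res.indices) == list(range(3, 9))
        assert not res.empty

    def test_zero_threshold_keeps_everything(self):
        traj, _ = generate_scripted(_blocks_scenario([2, 3, 5]))
        res = filter_frames(traj, build_gag("HP"), min_bound=0)
        assert list(res.indices) == list(range(9))

    def test_empty_result_flagged_not_fatal(self):
        traj, _ = generate_scripted(_blocks_scenario([0, 1]))
        res = filter_frames(traj, build_gag("HP"), min_bound=9)
        assert res.empty and len(res.indices) == 0

    def test_matches_per_frame_counts(self):
        counts = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
        traj, _ = generate_scripted(_blocks_scenario(counts, frames_per_block=1))
        chain = build_gag("HP")
        res = filter_frames(traj, chain, min_bound=4)
        oracle = contact_fractions(traj, chain).bound_counts
        assert list(res.indices) == [f for f, c in enumerate(oracle) if c >= 4]
        assert list(res.bound_counts) == counts


class TestPerDrugNormalize:
    @pytest.mark.parametrize(
        "total, n, expected",
        [(-13.0, 2, -6.5), (-3263.4, 10, -326.3), (-20.3, 10, -2.0)],
    )
    def test_published_cells(self, total, n, expected):
        comp = EnergyComponents(total, 0, 0, 0, 0, n)
        assert per_drug_normalize(comp)["dg"]["rounded"] == expected

    def test_half_rounds_away_from_zero(self):
        comp = EnergyComponents(-55.5, 0, 0, 0, 0, 10)
        assert per_drug_normalize(comp)["dg"]["rounded"] == -5.6

    def test_zero_drugs_rejected(self):
        with pytest.raises(ValueError):
            per_drug_normalize(EnergyComponents(1, 1, 1, 1, 1, 0))


class TestAdditivity:
    def test_consistent_record_passes(self):
        comp = EnergyComponents(-13.0, -15.1, 44.6, -1.0, 3.1, 2)
        res = additivity_check(comp)
        assert res.passed and res.residual == pytest.approx(0.0, abs=1e-9)

    def test_rounding_level_residual_passes(self):
        comp = EnergyComponents(-55.0, -44.6, -3263.4, -5.1, -5.4, 10)
        res = additivity_check(comp)
        assert res.passed and abs(res.residual) == pytest.approx(0.1)

    def test_inconsistent_record_fails(self):
        comp = EnergyComponents(-10.0, -5.0, 0.0, -2.0, -2.0, 2)
        assert not additivity_check(comp).passed

    def test_published_desulfated_row_is_inconsistent(self):
        """The published deHP row does not satisfy the decomposition: the
        residual is -0.7 kcal/mol, far beyond rounding noise."""
        row = ENERGY_TABLE.set_index("system").loc["deHP"]
        comp = EnergyComponents(row["dg"], row["vdw"], row["eel"],
                                row["esurf"], row["eel_plus_egb"], 7)
        res = additivity_check(comp)
        assert not res.passed
        assert res.residual == pytest.approx(-0.7, abs=1e-9)


class TestReferenceReproduction:
    def test_flags_exactly_the_dehp_anomalies(self):
        table = reproduce_reference_table().set_index("system")
        for system in table.index:
            for comp in ("dg", "vdw", "eel", "esurf", "eel_plus_egb"):
                flag = table.loc[system, f"{comp}_per_drug_match"]
                if system == "deHP" and comp in ("dg", "eel", "eel_plus_egb"):
                    assert not flag, (system, comp)
                else:
                    assert flag, (system, comp)
        # the anomalous cells are exactly what dividing by 10 produces
        assert table.loc["deHP", "per_drug_divisor_10"]

    def test_additivity_column(self):
        table = reproduce_reference_table().set_index("system")
        assert not table.loc["deHP", "additivity_pass"]
        others = table.drop(index="deHP")
        assert others["additivity_pass"].all()
        assert others["additivity_residual"].abs().max() <= 0.15


class TestSurrogate:
    def test_all_components_vanish_at_infinite_separation(self):
        scenario = Scenario(n_frames=1, mb_count=3, gag_preset="deHP",
                            script=[MBState()] * 3)
        traj, _ = generate_scripted(scenario)
        # push everything extremely far apart
        for i, mb in enumerate(traj.mb_ids):
            idx = np.flatnonzero(traj.topology["molecule_id"] == mb)
            traj.coords[0, idx] += np.array([1e6 * (i + 1), 0, 0])
        comp = surrogate_energy(traj, 0, build_gag("deHP"))
        for value in (comp.dg, comp.vdw, comp.eel, comp.esurf,
                      comp.eel_plus_egb):
            assert value == pytest.approx(0.0, abs=1e-6)

    def test_more_sites_give_stronger_electrostatics(self):
        """HP vs deHP with identical MB poses: |eel| strictly larger for
        the sulfated chain."""
        script = [MBState(bound=True, site_index=9), MBState()]
        hp, _ = generate_scripted(
            Scenario(n_frames=1, mb_count=2, gag_preset="HP", script=script)
        )
        dehp, _ = generate_scripted(
            Scenario(n_frames=1, mb_count=2, gag_preset="deHP",
                     script=[MBState(bound=True, site_index=1), MBState()])
        )
        e_hp = surrogate_energy(hp, 0, build_gag("HP")).eel
        e_dehp = surrogate_energy(dehp, 0, build_gag("deHP")).eel
        assert abs(e_hp) > abs(e_dehp)
        assert e_hp < 0  # attraction between cationic dye and anionic sites

    def test_permutation_invariance(self):
        traj, _ = generate_scripted(
            Scenario(n_frames=1, mb_count=2, gag_preset="CS4",
                     script=[MBState(bound=True, site_index=0), MBState()])
        )
        swapped = traj.coords.copy()
        top = traj.topology
        i1 = np.flatnonzero(top["molecule_id"] == "MB1")
        i2 = np.flatnonzero(top["molecule_id"] == "MB2")
        swapped[0, i1], swapped[0, i2] = (traj.coords[0, i2].copy(),
                                          traj.coords[0, i1].copy())
        from mbgag.trajectory import Trajectory
        traj2 = Trajectory(swapped, top)
        a = surrogate_energy(traj, 0, build_gag("CS4"))
        b = surrogate_energy(traj2, 0, build_gag("CS4"))
        assert a.dg == pytest.approx(b.dg, abs=1e-9)
        assert a.eel == pytest.approx(b.eel, abs=1e-9)

    def test_additivity_by_construction(self):
        traj, _ = generate_scripted(
            Scenario(n_frames=1, mb_count=2, gag_preset="HS2",
                     script=[MBState(bound=True), MBState(bound=True)])
        )
        comp = surrogate_energy(traj, 0, build_gag("HS2"))
        assert additivity_check(comp, tol=1e-9).passed


def test_component_table_round_trip(tmp_path):
    df = ENERGY_TABLE.head(2)[["dg", "vdw", "eel", "esurf", "eel_plus_egb"]]
    df = df.assign(frame=range(len(df)))
    path = tmp_path / "comps.tsv"
    df.to_csv(path, sep="\t", index=False)
    loaded = read_components_tsv(path)
    comp = aggregate_components(loaded, n_drugs=2)
    assert comp.dg == pytest.approx(df["dg"].mean())
    assert comp.egb == pytest.approx(comp.eel_plus_egb - comp.eel)


def test_component_table_missing_columns_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("frame\tdg\n0\t-1.0\n")
    with pytest.raises(ValueError, match="missing"):
        read_components_tsv(path)
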