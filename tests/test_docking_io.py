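import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from docktriage.docking_io import (
    DockingRun,
    ParseError,
    RamachandranSummary,
    build_energy_matrix,
    classify_model_quality,
    parse_energy_table,
    parse_pose_file,
    representative_energy,
    write_pose_file,
)

finite_energy = st.floats(
    min_value=-20.0, max_value=5.0, allow_nan=False, allow_infinity=False
)
energy_lists = st.lists(finite_energy, min_size=1, max_size=25)


class TestParsePoseFile:
    def test_single_block(self):
        text = "MODEL 1\nREMARK VINA RESULT:    -7.0    0.000    0.000\nENDMDL\n"
        assert parse_pose_file(text) == [-7.0]

    def test_three_blocks_in_file_order(self):
        run = DockingRun("c1", "ERK2", (-7.2, -6.9, -6.5))
        assert parse_pose_file(write_pose_file(run)) == [-7.2, -6.9, -6.5]

    def test_ignores_non_result_content(self):
        text = (
            "MODEL 1\nREMARK VINA RESULT: -5.5 0.0 0.0\n"
            "ATOM      1  C   LIG A   1       0.0 0.0 0.0\n"
            "REMARK  Name = ligand\nENDMDL\n"
        )
        assert parse_pose_file(text) == [-5.5]

    def test_no_result_line_is_parse_error(self):
        with pytest.raises(ParseError, match="no 'REMARK VINA RESULT:'"):
            parse_pose_file("MODEL 1\nATOM ...\nENDMDL\n")

    def test_malformed_energy_reports_line_number(self):
        text = "MODEL 1\nREMARK VINA RESULT: oops 0.0 0.0\nENDMDL\n"
        with pytest.raises(ParseError, match=":2:"):
            parse_pose_file(text)

    @given(energies=energy_lists)
    @settings(max_examples=50, deadline=None)
    def test_write_parse_round_trip(self, energies):
        run = DockingRun("c", "t", tuple(energies))
        assert parse_pose_file(write_pose_file(run)) == list(
            run.configuration_energies
        )


class TestParseEnergyTable:
    def test_single_row(self):
        text = "compound_id,target_id,configuration_index,energy_kcal_mol\nc1,ERK2,1,-7.0\n"
        runs = parse_energy_table(text)
        assert len(runs) == 1
        assert runs[0].configuration_energies == (-7.0,)

    def test_two_pairs_two_configs(self):
        text = (
            "compound_id\ttarget_id\tconfiguration_index\tenergy_kcal_mol\n"
            "c1\tERK2\t1\t-7.0\nc1\tERK2\t2\t-6.5\n"
            "c2\tERK2\t1\t-5.0\nc2\tERK2\t2\t-4.5\n"
        )
        runs = parse_energy_table(text)
        assert [len(r.configuration_energies) for r in runs] == [2, 2]

    def test_shuffled_rows_equal_sorted_rows(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"c{i}", t, k, round(float(rng.normal(-6, 1)), 3))
            for i in range(3)
            for t in ("ERK2", "p38")
            for k in range(1, 4)
        ]
        header = "compound_id,target_id,configuration_index,energy_kcal_mol\n"
        sorted_text = header + "".join(f"{a},{b},{c},{d}\n" for a, b, c, d in rows)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        shuf_text = header + "".join(f"{a},{b},{c},{d}\n" for a, b, c, d in shuffled)
        assert parse_energy_table(shuf_text) == parse_energy_table(sorted_text)

    def test_duplicate_triple_is_error(self):
        text = (
            "compound_id,target_id,configuration_index,energy_kcal_mol\n"
            "c1,ERK2,1,-7.0\nc1,ERK2,1,-6.0\n"
        )
        with pytest.raises(ParseError, match="duplicate"):
            parse_energy_table(text)

    def test_non_numeric_energy_reports_row(self):
        text = (
            "compound_id,target_id,configuration_index,energy_kcal_mol\n"
            "c1,ERK2,1,-7.0\nc1,ERK2,2,bad\n"
        )
        with pytest.raises(ParseError, match="row 3"):
            parse_energy_table(text)

    def test_missing_configuration_index_keeps_file_order(self):
        text = (
            "compound_id,target_id,energy_kcal_mol\n"
            "c1,ERK2,-7.0\nc1,ERK2,-6.5\nc1,ERK2,-8.0\n"
        )
        (run,) = parse_energy_table(text)
        assert run.configuration_energies == (-7.0, -6.5, -8.0)


class TestRepresentativeEnergy:
    @pytest.mark.parametrize(
        "energies, mode, expected",
        [
            ((-7.2, -6.9, -6.5), "minimum", -7.2),
            ((-7.2, -6.9, -6.5), "mean", -6.866666666666667),
            ((-5.0,), "minimum", -5.0),
            ((-5.0,), "mean", -5.0),
        ],
    )
    def test_reduction(self, energies, mode, expected):
        run = DockingRun("c", "t", energies)
        assert representative_energy(run, mode) == pytest.approx(expected, abs=1e-9)

    def test_empty_energies_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no configuration energies"):
            DockingRun("c", "t", ())

    def test_non_finite_energy_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            DockingRun("c", "t", (math.nan,))

    @given(energies=energy_lists)
    @settings(max_examples=100, deadline=None)
    def test_minimum_never_exceeds_mean(self, energies):
        run = DockingRun("c", "t", tuple(energies))
        assert representative_energy(run, "minimum") <= representative_energy(
            run, "mean"
        ) + 1e-12


class TestBuildEnergyMatrix:
    def test_one_by_one(self):
        m = build_energy_matrix([DockingRun("c1", "t1", (-7.0,))], ["c1"], ["t1"])
        assert m.loc["c1", "t1"] == -7.0

    def test_cellwise_matches_representative_energy(self):
        rng = np.random.default_rng(3)
        runs = [
            DockingRun(c, t, tuple(rng.normal(-6, 1, size=5)))
            for c in ("c1", "c2")
            for t in ("t1", "t2")
        ]
        for mode in ("minimum", "mean"):
            m = build_energy_matrix(runs, ["c1", "c2"], ["t1", "t2"], mode)
            for run in runs:
                assert m.loc[run.compound_id, run.target_id] == pytest.approx(
                    representative_energy(run, mode)
                )

    def test_missing_pair_names_it(self):
        runs = [
            DockingRun("c1", "t1", (-7.0,)),
            DockingRun("c1", "t2", (-6.0,)),
            DockingRun("c2", "t1", (-5.0,)),
        ]
        with pytest.raises(ValueError, match=r"\('c2', 't2'\)"):
            build_energy_matrix(runs, ["c1", "c2"], ["t1", "t2"])

    def test_unrequested_pair_dropped_with_warning(self):
        runs = [
            DockingRun("c1", "t1", (-7.0,)),
            DockingRun("c9", "t1", (-6.0,)),
        ]
        with pytest.warns(UserWarning, match="unrequested"):
            m = build_energy_matrix(runs, ["c1"], ["t1"])
        assert list(m.index) == ["c1"]

    def test_permutation_invariant_in_run_order(self):
        rng = np.random.default_rng(11)
        runs = [
            DockingRun(f"c{i}", f"t{j}", tuple(rng.normal(-6, 1, size=4)))
            for i in range(3)
            for j in range(2)
        ]
        compounds = [f"c{i}" for i in range(3)]
        targets = [f"t{j}" for j in range(2)]
        base = build_energy_matrix(runs, compounds, targets)
        rng.shuffle(runs)
        pd.testing.assert_frame_equal(
            base, build_energy_matrix(runs, compounds, targets)
        )


class TestReadEnergyMatrixXlsx:
    def test_round_trip_synthetic_workbook(self, tmp_path):
        """A synthetic score sheet (header row of proteins, compound name
        column) reads back as the original matrix."""
        from docktriage.docking_io import read_energy_matrix_xlsx

        rng = np.random.default_rng(6)
        expected = pd.DataFrame(
            np.round(rng.normal(-6, 1, size=(4, 5)), 1),
            index=[f"compound {i}" for i in range(4)],
            columns=["ERK2", "JNK2", "p38", "p65", "IkBa"],
        )
        path = tmp_path / "scores.xlsx"
        expected.to_excel(path)
        got = read_energy_matrix_xlsx(path)
        pd.testing.assert_frame_equal(got, expected, check_names=False)


class TestModelQuality:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (90.3, "good"),
            (92.2, "good"),
            (90.8, "good"),
            (79.0, "not_good"),
            (80.9, "not_good"),
            (90.0, "not_good"),  # strictly-greater boundary
        ],
    )
    def test_rule(self, pct, expected):
        assert classify_model_quality(RamachandranSummary("p", pct)) == expected

    def test_out_of_range_percentage(self):
        with pytest.raises(ValueError):
            RamachandranSummary("p", 101.0)

    @given(
        lo=st.floats(min_value=0, max_value=100, allow_nan=False),
        hi=st.floats(min_value=0, max_value=100, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_percentage(self, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        order = {"not_good": 0, "good": 1}
        assert (
            order[classify_model_quality(RamachandranSummary("p", lo))]
            <= order[classify_model_quality(RamachandranSummary("p", hi))]
        )
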