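"""Hypnogram model, harmonization operations and file round-trips."""

import numpy as np
import pytest

from hypnoval.errors import (
    AlignmentError,
    ContiguityError,
    FormatError,
    GridError,
    MappingError,
    WindowError,
)
from hypnoval.hypnogram import (
    AlignedPair,
    Hypnogram,
    align_pair,
    broadcast,
    extract_episodes,
    map_stages,
    read_hypnogram,
    restrict_window,
    smooth_majority,
    stage_changes,
    write_hypnogram,
)
from hypnoval.stages import DEVICE5, HARMONIZED4, PSG5

from conftest import random_hypnogram


class TestIO:
    def test_transcription(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("onset_s,duration_s,stage\n0,30,WAKE\n30,30,N2\n60,30,N2\n")
        h = read_hypnogram(p, PSG5)
        assert h.n_epochs == 3
        assert h.epoch_s == 30
        # consecutive identical rows stay distinct epochs
        assert h.stages == ("WAKE", "N2", "N2")

    def test_gap_is_contiguity_error(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("onset_s,duration_s,stage\n0,30,WAKE\n60,30,N2\n")
        with pytest.raises(ContiguityError):
            read_hypnogram(p, PSG5)

    def test_unknown_stage_names_row(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("onset_s,duration_s,stage\n0,30,WAKE\n30,30,XX\n")
        with pytest.raises(FormatError, match="line 3"):
            read_hypnogram(p, PSG5)

    def test_non_uniform_duration(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("onset_s,duration_s,stage\n0,30,WAKE\n30,60,N2\n")
        with pytest.raises(GridError):
            read_hypnogram(p, PSG5)

    def test_round_trip_identity_random_files(self, tmp_path, rng):
        for i in range(100):
            vocab = [PSG5, DEVICE5, HARMONIZED4][i % 3]
            n = int(rng.integers(1, 50))
            h = Hypnogram(
                f"S{i}", "truth", float(rng.integers(0, 10)) * 30.0,
                30.0 if i % 2 else 360.0,
                tuple(rng.choice(vocab.stages, size=n)), vocab,
            )
            path = tmp_path / f"h{i}.csv"
            write_hypnogram(h, path)
            assert read_hypnogram(path) == h

    def test_metadata_lines_parsed(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text(
            "# subject_id=S042\n# source=device\n# vocabulary=DEVICE5\n"
            "onset_s,duration_s,stage\n0,360,ABSENT\n360,360,LIGHT\n"
        )
        h = read_hypnogram(p)
        assert (h.subject_id, h.source, h.vocabulary.name) == ("S042", "device", "DEVICE5")


class TestMapStages:
    def test_default_pools_nrem_depth(self):
        h = Hypnogram("s", "r1", 0, 30, ("N1", "N2", "N3", "REM", "WAKE"), PSG5)
        assert map_stages(h).stages == ("LIGHT", "LIGHT", "DEEP", "REM", "WAKE")

    def test_identity_mapping(self):
        h = Hypnogram("s", "r1", 0, 30, ("WAKE", "REM"), HARMONIZED4)
        ident = {s: s for s in HARMONIZED4.stages}
        assert map_stages(h, ident, HARMONIZED4).stages == h.stages

    def test_matches_elementwise_lookup(self, rng):
        h = random_hypnogram(rng, 500, PSG5)
        from hypnoval.stages import PSG5_TO_HARMONIZED4

        assert map_stages(h).stages == tuple(PSG5_TO_HARMONIZED4[s] for s in h.stages)

    def test_partial_mapping_rejected(self):
        h = Hypnogram("s", "r1", 0, 30, ("N1", "REM"), PSG5)
        with pytest.raises(MappingError):
            map_stages(h, {"N1": "LIGHT"}, HARMONIZED4)

    def test_timing_preserved(self, rng):
        h = random_hypnogram(rng, 40, PSG5, onset_s=90.0)
        m = map_stages(h)
        assert (m.onset_s, m.epoch_s, m.n_epochs) == (h.onset_s, h.epoch_s, h.n_epochs)


class TestSmoothMajority:
    def test_uniform_window(self):
        h = Hypnogram("s", "c", 0, 30, ("LIGHT",) * 12, HARMONIZED4)
        assert smooth_majority(h).stages == ("LIGHT",)

    def test_majority_wins(self):
        h = Hypnogram("s", "c", 0, 30, ("LIGHT",) * 7 + ("DEEP",) * 5, HARMONIZED4)
        assert smooth_majority(h).stages == ("LIGHT",)

    def test_tie_breaks_by_priority(self):
        h = Hypnogram("s", "c", 0, 30, ("WAKE",) * 6 + ("LIGHT",) * 6, HARMONIZED4)
        assert smooth_majority(h).stages == ("WAKE",)
        h2 = Hypnogram("s", "c", 0, 30, ("DEEP",) * 6 + ("REM",) * 6, HARMONIZED4)
        assert smooth_majority(h2).stages == ("REM",)

    def test_trailing_partial_window_scored(self):
        h = Hypnogram("s", "c", 0, 30, ("LIGHT",) * 12 + ("DEEP", "DEEP", "REM"), HARMONIZED4)
        assert smooth_majority(h).stages == ("LIGHT", "DEEP")

    def test_brute_force_counter_oracle(self, rng):
        """Every output window equals the arg-max of a brute-force counter."""
        priority = ("WAKE", "REM", "DEEP", "LIGHT")
        for _ in range(120):
            n = int(rng.integers(1, 60))
            h = random_hypnogram(rng, n)
            sm = smooth_majority(h)
            windows = [h.stages[i : i + 12] for i in range(0, n, 12)]
            assert len(sm.stages) == len(windows)
            for got, window in zip(sm.stages, windows):
                best = max(window.count(s) for s in set(window))
                winners = [s for s in priority if window.count(s) == best]
                assert got == winners[0]

    def test_duration_conserved(self, rng):
        h = random_hypnogram(rng, 48)
        assert smooth_majority(h).duration_s == h.duration_s


class TestBroadcast:
    def test_replication(self):
        h = Hypnogram("s", "d", 0, 360, ("REM",), HARMONIZED4)
        out = broadcast(h)
        assert out.stages == ("REM",) * 12 and out.epoch_s == 30

    def test_smooth_after_broadcast_is_identity(self, rng):
        for _ in range(20):
            h = random_hypnogram(rng, int(rng.integers(1, 30)), epoch_s=360.0)
            assert smooth_majority(broadcast(h)) == h

    def test_non_divisible_grid(self):
        h = Hypnogram("s", "d", 0, 100, ("REM",), HARMONIZED4)
        with pytest.raises(GridError):
            broadcast(h, 30.0)


class TestRestrictWindow:
    def test_full_span_identity(self, rng):
        h = random_hypnogram(rng, 10)
        assert restrict_window(h, h.onset_s, h.end_s) == h

    def test_prefix(self, rng):
        h = random_hypnogram(rng, 4)
        out = restrict_window(h, 0, 60)
        assert out.stages == h.stages[:2]

    def test_partial_edge_epochs_drop(self, rng):
        h = random_hypnogram(rng, 4)
        # [45, 75) contains no fully-included 30-s epoch
        with pytest.raises(WindowError):
            restrict_window(h, 45, 75)

    def test_interior_window(self, rng):
        h = random_hypnogram(rng, 6)
        out = restrict_window(h, 30, 150)
        assert out.stages == h.stages[1:5]
        assert out.onset_s == 30


class TestEpisodes:
    def test_run_length_oracle_example(self):
        h = Hypnogram("s", "c", 0, 30, ("WAKE", "WAKE", "LIGHT", "LIGHT", "LIGHT", "WAKE"), HARMONIZED4)
        eps = extract_episodes(h)
        assert [(e.stage, e.start_epoch, e.length_epochs) for e in eps] == [
            ("WAKE", 0, 2), ("LIGHT", 2, 3), ("WAKE", 5, 1)
        ]
        assert sum(1 for e in eps if e.stage == "WAKE") == 2

    def test_constant_and_alternating(self):
        const = Hypnogram("s", "c", 0, 30, ("REM",) * 9, HARMONIZED4)
        assert len(extract_episodes(const)) == 1
        alt = Hypnogram("s", "c", 0, 30, ("WAKE", "REM") * 5, HARMONIZED4)
        assert len(extract_episodes(alt)) == 10

    def test_lengths_partition_sequence(self, rng):
        for _ in range(50):
            h = random_hypnogram(rng, int(rng.integers(1, 100)))
            eps = extract_episodes(h)
            assert sum(e.length_epochs for e in eps) == h.n_epochs
            # consecutive episodes differ in stage
            assert all(a.stage != b.stage for a, b in zip(eps, eps[1:]))
            assert stage_changes(h) == len(eps) - 1


class TestAlignPair:
    def _consensus(self, stages):
        return Hypnogram("s", "consensus", 0, 30, stages, PSG5)

    def test_identity_sources(self, rng):
        truth = random_hypnogram(rng, 48, PSG5)
        device = broadcast(
            smooth_majority(map_stages(truth)), 30.0
        )  # what a zero-error device reports, already harmonized
        from hypnoval.hypnogram import Hypnogram as H

        dev6 = smooth_majority(map_stages(truth))
        pair = align_pair(truth, dev6)
        assert all(pair.valid_mask)
        assert pair.reference == pair.device

    def test_leading_absent_masked(self, rng):
        truth = random_hypnogram(rng, 48, PSG5)
        smoothed = smooth_majority(map_stages(truth))
        dev_stages = ("ABSENT",) * 2 + tuple(
            s if s != "ABSENT" else "WAKE" for s in smoothed.stages
        )
        device = Hypnogram("s", "device", -2 * 360.0, 360.0, dev_stages, DEVICE5)
        pair = align_pair(truth, device, absent_policy="exclude")
        # overlap starts at the reference onset; ABSENT windows lie before it
        assert pair.window_origin_s == 0.0
        assert all(pair.valid_mask)

        # interior absence: mask out those 12 comparison epochs
        dev2 = Hypnogram(
            "s", "device", 0.0, 360.0,
            ("ABSENT",) + tuple(smoothed.stages[1:]), DEVICE5,
        )
        pair2 = align_pair(truth, dev2, absent_policy="exclude")
        assert pair2.valid_mask[:12] == (False,) * 12
        assert all(pair2.valid_mask[12:])

    def test_absent_as_wake_policy(self, rng):
        truth = random_hypnogram(rng, 48, PSG5)
        smoothed = smooth_majority(map_stages(truth))
        dev = Hypnogram(
            "s", "device", 0.0, 360.0,
            ("ABSENT",) + tuple(smoothed.stages[1:]), DEVICE5,
        )
        pair = align_pair(truth, dev, absent_policy="as_wake")
        assert all(pair.valid_mask)
        assert pair.device[:12] == ("WAKE",) * 12

    def test_no_overlap_raises(self, rng):
        truth = random_hypnogram(rng, 12, PSG5)
        dev = Hypnogram("s", "device", 9_000.0, 360.0, ("LIGHT",), DEVICE5)
        with pytest.raises(AlignmentError):
            align_pair(truth, dev)

    def test_off_grid_device_raises(self, rng):
        truth = random_hypnogram(rng, 12, PSG5)
        dev = Hypnogram("s", "device", 17.0, 360.0, ("LIGHT",), DEVICE5)
        with pytest.raises(GridError):
            align_pair(truth, dev)
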