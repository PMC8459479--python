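import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqsonify.algorithms import (
    NoteEvent,
    SonificationParams,
    count_velocity,
    sonify_combined,
    sonify_hydrophobicity,
    sonify_msa_entropy,
    sonify_msa_hydrophobicity,
    sonify_reduced,
)
from seqsonify.entropy import entropy_profile
from seqsonify.errors import PitchLookupError
from seqsonify.pitch_maps import ges_scale
from seqsonify.sequence_io import (
    STANDARD_RESIDUES,
    Alignment,
    ProteinSequence,
    ResiduePolicy,
)

residues_st = st.text(alphabet=sorted(STANDARD_RESIDUES), min_size=1, max_size=60)


def seq(residues, policy=ResiduePolicy.STRICT):
    return ProteinSequence(id="t", residues=residues, policy=policy)


class TestNoteEvent:
    def test_valid(self):
        ev = NoteEvent(onset=0, midi_pitch=60)
        assert ev.duration == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"onset": -1, "midi_pitch": 60},
            {"onset": 0, "midi_pitch": 128},
            {"onset": 0, "midi_pitch": 60, "velocity": 0},
            {"onset": 0, "midi_pitch": 60, "velocity": 128},
            {"onset": 0, "midi_pitch": 60, "duration": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            NoteEvent(**kwargs)


class TestAlgorithmI:
    def test_single_f(self):
        track = sonify_hydrophobicity(seq("F"))
        assert len(track.events) == 1
        assert track.events[0].midi_pitch == 50
        assert track.events[0].onset == 0
        assert track.events[0].voice == "sine"

    def test_fr_pitches_and_onsets(self):
        track = sonify_hydrophobicity(seq("FR"))
        assert [e.midi_pitch for e in track.events] == [50, 77]
        assert [e.onset for e in track.events] == [0, 1]

    def test_task1_event_count(self, task1_protein):
        track = sonify_hydrophobicity(task1_protein.sequence)
        assert len(track.events) == 253
        assert track.slots_total == 253

    def test_source_positions_one_based(self):
        track = sonify_hydrophobicity(seq("FRD"))
        assert [e.source_position for e in track.events] == [1, 2, 3]
        assert [e.source_symbol for e in track.events] == ["F", "R", "D"]

    def test_permissive_unknown_is_silent_slot(self):
        track = sonify_hydrophobicity(
            seq("FXR", policy=ResiduePolicy.PERMISSIVE),
            SonificationParams(residue_policy=ResiduePolicy.PERMISSIVE),
        )
        assert [e.onset for e in track.events] == [0, 2]  # slot 1 silent
        assert track.slots_total == 3

    def test_strict_unknown_raises(self):
        with pytest.raises(PitchLookupError):
            sonify_hydrophobicity(seq("FXR", policy=ResiduePolicy.PERMISSIVE))

    def test_invert_polarity_reflects_within_scale(self):
        normal = sonify_hydrophobicity(seq("FR"))
        flipped = sonify_hydrophobicity(
            seq("FR"), SonificationParams(invert_polarity=True)
        )
        assert [e.midi_pitch for e in flipped.events] == [77, 50]
        assert {e.midi_pitch for e in flipped.events} == {
            e.midi_pitch for e in normal.events
        }

    @given(residues_st)
    def test_one_event_per_residue(self, residues):
        track = sonify_hydrophobicity(seq(residues))
        assert len(track.events) == len(residues)
        assert [e.onset for e in track.events] == list(range(len(residues)))

    @given(residues_st)
    def test_deterministic_pitch_per_residue(self, residues):
        track = sonify_hydrophobicity(seq(residues))
        scale = ges_scale()
        assert [e.midi_pitch for e in track.events] == [
            scale.pitch(r) for r in residues
        ]


class TestAlgorithmII:
    def test_one_residue_per_group(self):
        track = sonify_reduced(seq("FAKD"))
        assert [e.midi_pitch for e in track.events] == [67, 64, 62, 60]

    def test_constant_pitch_run(self):
        track = sonify_reduced(seq("FILVWY"))
        assert [e.midi_pitch for e in track.events] == [67] * 6

    @given(residues_st)
    def test_pitch_set_is_pentatonic_subset(self, residues):
        track = sonify_reduced(seq(residues))
        assert {e.midi_pitch for e in track.events} <= {60, 62, 64, 67}

    def test_voice_is_sine(self):
        track = sonify_reduced(seq("FAKD"))
        assert {e.voice for e in track.events} == {"sine"}

    def test_invert_polarity_swaps_extreme_groups(self):
        track = sonify_reduced(seq("FAKD"), SonificationParams(invert_polarity=True))
        assert [e.midi_pitch for e in track.events] == [60, 62, 64, 67]


class TestAlgorithmIII:
    def test_f_piano(self):
        track = sonify_combined(seq("F"))
        assert track.events[0].midi_pitch == 50
        assert track.events[0].voice == "piano"

    def test_d_tb303(self):
        track = sonify_combined(seq("D"))
        assert track.events[0].midi_pitch == 73
        assert track.events[0].voice == "tb303"

    @given(residues_st)
    def test_pitch_stream_equals_algorithm_i(self, residues):
        combined = sonify_combined(seq(residues))
        hydro = sonify_hydrophobicity(seq(residues))
        assert [e.midi_pitch for e in combined.events] == [
            e.midi_pitch for e in hydro.events
        ]

    def test_four_voices_on_representative_input(self):
        track = sonify_combined(seq("FAKD"))
        assert [e.voice for e in track.events] == [
            "piano", "sine", "pluck", "tb303",
        ]


class TestAlgorithmIV:
    def test_conserved_alignment_all_middle_c(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("AAAA", "AAAA", "AAAA"))
        track = sonify_msa_entropy(aln)
        assert len(track.events) == 4
        assert [e.midi_pitch for e in track.events] == [60] * 4

    def test_one_event_per_column(self, task2_msa):
        track = sonify_msa_entropy(task2_msa.alignment)
        assert len(track.events) == task2_msa.alignment.n_cols
        assert [e.onset for e in track.events] == list(
            range(task2_msa.alignment.n_cols)
        )

    def test_monophonic(self, task2_msa):
        track = sonify_msa_entropy(task2_msa.alignment)
        onsets = [e.onset for e in track.events]
        assert len(onsets) == len(set(onsets))

    def test_max_diversity_column_carries_max_pitch(self):
        # last column maximally diverse, others conserved or mildly varied
        aln = Alignment(
            ids=("a", "b", "c", "d"),
            rows=("AAAF", "AAAC", "AACD", "AAAE"),
        )
        track = sonify_msa_entropy(aln)
        profile = entropy_profile(aln)
        top_column = max(range(4), key=lambda i: profile.values[i])
        assert top_column == 3
        pitches = [e.midi_pitch for e in track.events]
        assert pitches[3] == max(pitches)

    def test_voice_is_saw(self, small_alignment):
        track = sonify_msa_entropy(small_alignment)
        assert {e.voice for e in track.events} == {"saw"}

    def test_invert_polarity_reverses_order(self):
        aln = Alignment(
            ids=("a", "b", "c", "d"),
            rows=("AAAF", "AAAC", "AACD", "AAAE"),
        )
        normal = sonify_msa_entropy(aln)
        flipped = sonify_msa_entropy(aln, SonificationParams(invert_polarity=True))
        normal_pitches = [e.midi_pitch for e in normal.events]
        flipped_pitches = [e.midi_pitch for e in flipped.events]
        assert flipped_pitches.index(max(flipped_pitches)) == (
            normal_pitches.index(min(normal_pitches))
        )


class TestAlgorithmV:
    def test_consensus_column_loud(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("F", "F", "F"))
        track = sonify_msa_hydrophobicity(aln)
        assert len(track.events) == 1
        assert track.events[0].midi_pitch == 50
        assert track.events[0].velocity == 127  # count 3 of 3

    def test_mostly_gaps_quiet(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("F", "-", "-"))
        track = sonify_msa_hydrophobicity(aln)
        assert len(track.events) == 1
        assert track.events[0].midi_pitch == 50
        assert track.events[0].velocity == count_velocity(1, 3)
        assert track.events[0].velocity < 127

    def test_all_gap_column_silent(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("F-", "F-", "F-"))
        track = sonify_msa_hydrophobicity(aln)
        assert all(e.onset == 0 for e in track.events)

    def test_one_event_per_distinct_residue_per_column(self, task2_msa):
        aln = task2_msa.alignment
        track = sonify_msa_hydrophobicity(aln)
        expected = sum(
            len(set(aln.column(i)) - {"-"}) for i in range(aln.n_cols)
        )
        assert len(track.events) == expected

    def test_velocity_strictly_increasing_in_count(self):
        # columns with counts 1..5 of residue F among 5 rows
        columns = ["F" * c + "-" * (5 - c) for c in range(1, 6)]
        rows = ["".join(col[r] for col in columns) for r in range(5)]
        aln = Alignment(ids=tuple("abcde"), rows=tuple(rows))
        track = sonify_msa_hydrophobicity(aln)
        velocities = [e.velocity for e in track.events]
        assert len(velocities) == 5
        assert velocities == sorted(velocities)
        assert all(a < b for a, b in zip(velocities, velocities[1:]))

    def test_polyphonic_shared_onsets(self):
        aln = Alignment(ids=("a", "b"), rows=("F", "R"))
        track = sonify_msa_hydrophobicity(aln)
        assert [e.onset for e in track.events] == [0, 0]
        assert {e.midi_pitch for e in track.events} == {50, 77}

    def test_distinct_pitches_match_distinct_residues(self, task2_msa):
        aln = task2_msa.alignment
        track = sonify_msa_hydrophobicity(aln)
        scale = ges_scale()
        for i in range(aln.n_cols):
            sounding = {
                e.midi_pitch for e in track.events if e.onset == i
            }
            expected = {
                scale.pitch(r) for r in set(aln.column(i)) - {"-"}
            }
            assert sounding == expected

    def test_voice_is_saw(self, small_alignment):
        track = sonify_msa_hydrophobicity(small_alignment)
        assert {e.voice for e in track.events} == {"saw"}


class TestCountVelocity:
    def test_bounds(self):
        assert count_velocity(5, 5) == 127
        assert count_velocity(1, 97) == 30 + round(97 / 97)  # near v_min

    def test_monotone(self):
        velocities = [count_velocity(c, 10) for c in range(1, 11)]
        assert all(a < b for a, b in zip(velocities, velocities[1:]))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            count_velocity(0, 5)
        with pytest.raises(ValueError):
            count_velocity(6, 5)


class TestTrackInvariants:
    @given(residues_st)
    def test_events_sorted_and_reproducible(self, residues):
        t1 = sonify_hydrophobicity(seq(residues))
        t2 = sonify_hydrophobicity(seq(residues))
        assert t1 == t2
        onsets = [e.onset for e in t1.events]
        assert onsets == sorted(onsets)

    def test_voices_in_first_appearance_order(self):
        track = sonify_combined(seq("DKAF"))
        assert track.voices == ("tb303", "pluck", "sine", "piano")

    def test_duration_seconds(self):
        track = sonify_hydrophobicity(
            seq("FRD"), SonificationParams(note_duration_seconds=0.5)
        )
        assert track.duration_seconds == pytest.approx(1.5)
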