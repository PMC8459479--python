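# seqsonify

Parameter-mapping sonification of protein sequences and protein multiple
sequence alignments (MSAs).  FASTA in, note events out — rendered as
standard MIDI files, Sonic Pi source code, or plain-text event tables.

Five algorithms are implemented:

| Algorithm | Input | Mapping |
|---|---|---|
| I `protein hydro` | single sequence | GES hydrophobicity scale → 20 pitches (F=50 … R=77), sine voice |
| II `protein reduced` | single sequence | four hydrophobicity groups → pentatonic pitches (FILVWY=67, ACGMP=64, KQST=62, DEHNR=60) |
| III `protein combined` | single sequence | GES pitch + one instrument per reduced group (piano/sine/pluck/tb303) |
| IV `msa entropy` | aligned FASTA | per-column Shannon entropy, z-score standardised to pitches centred on middle C (spread 10), saw voice |
| V `msa hydro` | aligned FASTA | polyphonic: one note per distinct non-gap residue per column at its GES pitch, volume scaled by residue count; gaps are silent |

Position maps to time throughout: one note-slot per residue or column.

## CLI

```sh
# sonify a protein with the hydrophobicity scale
seqsonify protein hydro protein.fasta --out protein.mid

# combined pitch+instrument mapping, emitted as Sonic Pi code
seqsonify protein combined protein.fasta --format sonicpi

# MSA entropy profile as a plain-text event table
seqsonify msa entropy aln.fasta --format events

# generate deterministic synthetic inputs
seqsonify fixtures repeat-protein --seed 1 --out task1.fasta
seqsonify fixtures domain-msa --seed 1 --gap-rate 0.3 --out task2.fasta
```

Common flags: `--format {midi,sonicpi,events}`, `--note-duration` (seconds
per slot, default 0.25), `--invert-polarity`, `--residue-policy
{strict,permissive}`, `--config FILE` (simple `key = value`: `program.<voice>`,
`note_duration`, `velocity`, `v_min`, `v_max`), `--record N` for
multi-record FASTA.  Strict policy (default) rejects residues outside the
20-letter alphabet; permissive renders them as silent rests.

The `fixtures` subcommands generate the two evaluation-task geometries —
a length-253 protein with an 8-residue motif repeated 4× in tandem, and a
5-sequence MSA with three conserved domains (<50 columns) — writing a
`.meta.txt` ground-truth sidecar next to the FASTA.

## Library

```python
from seqsonify import (
    read_fasta, sonify_hydrophobicity, write_midi,
    make_domain_msa, sonify_msa_entropy,
)

seq = read_fasta("protein.fasta")[0]
track = sonify_hydrophobicity(seq)
write_midi(track, "protein.mid")

msa = make_domain_msa(seed=1).alignment
entropy_track = sonify_msa_entropy(msa)
```

Modules: `sequence_io` (FASTA/aligned-FASTA and domain types),
`pitch_maps` (GES scale, reduced alphabet; the scale table also ships as
`data/ges_scale.csv`), `entropy` (column entropy + pitch standardisation),
`algorithms` (the five sonifications), `render` (MIDI / Sonic Pi /
event-table writers), `smf` (independent MIDI reader, used as a round-trip
test oracle), `fixtures` (seeded synthetic data), `cli`.

A note on the scale: the published pitch table is hard-coded as
authoritative.  The stated construction rule (previous pitch + GES score
increment, rounded up) is implemented separately in
`derive_scale_from_scores`; it agrees with the published table cell-wise
at 19 of 20 residues — glutamine (Q) is printed one semitone below what
the rule yields — and the canonical scale deliberately keeps the
published value.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(table fidelity, reduced-alphabet fidelity, entropy transform moments,
brute-force entropy oracle over 1,000 random columns, structural event
counts, MIDI round-trip/determinism).

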