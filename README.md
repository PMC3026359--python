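# hdx-prodyn

Peptide-level hydrogen/deuterium exchange mass-spectrometry (HDX-MS)
analysis, plus a ground-truth simulator so the whole pipeline can be
exercised and tested without instrument data.

The pipeline covers the classic peptide-level HDX workflow:

1. **Uptake quantification** (`uptake_core`) — intensity-weighted centroids
   of isotopic clusters, converted to deuteration percentages with
   back-exchange (recovery 0.70) and buffer-D2O-fraction (0.80) corrections
   against a computed (or measured) fully-deuterated reference.
2. **Differential statistics** (`differential_stats`) — two-sided paired
   Student t-tests over the last three labeling timepoints comparing a
   ligand-free (apo) and a ligand-bound (holo) condition, with
   protected / destabilized / not-significant classification.
3. **Structural projection** (`structure_conservation`) — peptide-level
   differences averaged onto residues, written into the B-factor column of
   a PDB (byte-preserving outside columns 61–66), and compared against
   multiple-sequence-alignment conservation (modal-symbol score, Spearman
   rank correlation).
4. **Bookkeeping** (`peptide_map`) — peptide location, sequence coverage,
   exchangeable-amide counting (N-terminal residue and prolines excluded),
   average/monoisotopic masses for formulas, peptides, and named ligands.
5. **Simulation** (`synthetic_data`) — first-order per-residue exchange
   kinetics with regional protection factors, exact natural isotopic
   envelopes from elemental composition, Poisson-binomial deuteron counts,
   independent per-deuteron back-exchange, and multiplicative lognormal
   intensity noise. Fully deterministic under a seed.

## Command line

```sh
# generate a synthetic experiment (peaks.csv, peptides.csv, protein.fasta, truth.json)
hdx-prodyn simulate --config sim.yaml --out data/ --seed 1

# check an input directory (exit 0/1/2 = ok/warnings/errors)
hdx-prodyn validate --in data/

# individual stages or everything at once
hdx-prodyn uptake  --in data/ --out results/
hdx-prodyn diff    --in data/ --out results/ --apo apo --holo xylan --alpha 0.05 --last-k 3
hdx-prodyn overlay --config analysis.yaml --in data/ --out results/
hdx-prodyn run     --config analysis.yaml --in data/ --out results/
hdx-prodyn report  --out results/
```

A minimal simulation config:

```yaml
seed: 1
noise_cv: 0.02
replicates: 2
design:
  conditions: [apo, xylohexaose, xylan]
  timepoints: [0, 60, 240, 960, 1920, 3840]
regions:
  - {start: 1,   end: 100, protection: {}}
  - {start: 101, end: 190, protection: {xylohexaose: 5.0, xylan: 2.0}}
```

An analysis config may additionally point at a structure and an alignment:

```yaml
files:
  structure: structure.pdb
  alignment: alignment.fasta
chain: A
alignment_reference: demo_xylanase
```

## File formats

All text. Peak lists are CSV with one row per peak
(`peptide_sequence,charge,condition,time_s,replicate,mz,intensity,sn_ratio`),
the peptide table is `sequence,start,end,charge,sn_ratio`, the protein is
FASTA, alignments are aligned FASTA or Clustal, structures are PDB v3.3.

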