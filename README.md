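# mutscan

Desk-scale analysis toolkit for activity selections on randomly mutated
receptor libraries, with a synthetic-data generator that stands in for the
wet-lab selections and molecular-dynamics runs.

The package covers four analysis stages plus data generation:

- **`mutscan.enrichment`** — per-variant frequencies from read-count tables
  and a three-filter pipeline nominating activating mutations: frequency
  `> 1%` in an activation-selected library, `> 8`-fold enrichment over a
  loss-of-function reference (zero reference frequencies get a
  `0.5 / coverage` pseudofrequency), and membership in a catalogue of
  cancer-listed substitutions. Coverage QC included.
- **`mutscan.flow_quant`** — rectangular and diagonal gating in log10
  space, geometric-mean fluorescence (gMFI), background subtraction and
  wild-type normalization, two-tailed paired t-tests, and bead-based
  surface-receptor calibration.
- **`mutscan.tm_hydropathy`** — Kyte-Doolittle profiles, a scan for
  hydrophilic substitutions located strictly more than a margin away from
  both ends of an annotated transmembrane span, and detection of
  small-x-x-x-small (and overlapping double) dimerization motifs.
- **`mutscan.energetics`** — Jarzynski and Crooks-Gaussian-intersection
  free-energy estimators from nonequilibrium work samples, and assembly of
  a thermodynamic cycle (insertion, N-dimer, C-dimer, pose change) with
  ddG derivation and loop-closure residuals. Reverse work is stored as the
  work of the reverse process; the Crooks comparison negates it internally.
- **`mutscan.traj_contacts`** — inter-motif minimum-distance time series,
  averaged residue-residue contact-distance maps, and geometric
  hydrogen-bond occupancy from multi-MODEL PDB trajectories (Angstrom in,
  nm throughout).
- **`mutscan.synthetic`** — generators for all of the above with known
  ground truth: exhaustive single-nucleotide-variant libraries, selection
  rounds with multinomial sequencing noise and C→T-biased PCR artifacts,
  two-channel flow events with an exponential phospho-vs-expression regime,
  Crooks-consistent Gaussian work samples, and idealized two-helix dimer
  trajectories in N- or C-pose with optional Gln-Gln hydrogen-bond
  placement.

## Command line

```sh
mutscan simulate counts --n-codons 100 --seed 1 --out counts.tsv
mutscan enrich run --counts counts.tsv --cosmic cosmic.tsv --freq 0.01 --fold 8
mutscan flow quant --events events.csv --expr-gate 1.5:3.5
mutscan tmscan --tm 646:668 --margin 5
mutscan simulate work --dg -49.2 --sigma 5 --n 100000 --out work.tsv
mutscan fe cgi --work work.tsv
mutscan simulate dimer --pose C --frames 100 --mutate 658=Q \
    --hbond-fraction 0.5 --out dimer.pdb
mutscan traj hbond --pdb dimer.pdb
```

Event tables are plain CSV (`expression, phospho, label`); native FCS
parsing is out of scope (convert upstream). Trajectories are multi-MODEL
PDB; other trajectory formats are documented extension points.

## Packaged fixtures

Small TSV fixtures under `mutscan/data/` support the worked examples: a
demonstration count table plus a mini catalogue of protein substitutions
with occurrence counts, and a transmembrane-neighborhood mutation table
with the segment sequence (precursor numbering, offset noted in the FASTA
header).
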