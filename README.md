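# gifp

GPCR–ligand interaction fingerprints and ligand-function classification:

- **complex I/O** — read PDB complexes, isolate one receptor chain and one
  orthosteric small-molecule ligand, attach Ballesteros–Weinstein (BW)
  generic-position annotations from a GPCRdb-style TSV table;
- **interactions** — geometric contact detection with five typed
  interaction classes (Hbond / Metal / Ionic / Arene / Distance, plus
  Covalent), a distance-based interaction score (1 at ≤ 3.23 Å, 0 at
  ≥ 4.63 Å, linear in between — so a 0.5 cutoff is a 3.93 Å cap), and
  documented surrogate per-contact energies;
- **fingerprints** — receptor-weighted interaction frequencies per BW site
  (each receptor counts equally however many complexes represent it) and
  thresholded 10–15-site fingerprints, globally or per activation state;
- **features** — BW-indexed interaction profiles (energy sum + top-2
  interaction types/energies per position) with strict NA / 'None' / 0
  semantics and the retained-position filter;
- **classify** — 75/25 split, ordinal encoding / mean imputation /
  standardization fitted on the training split, a 500-tree random forest
  (no bootstrap, depth 30, balanced-subsample class weights, √p features
  per split) with 10-fold CV, merged-active reconfiguration, majority-rule
  pose voting, and confusion-matrix metrics including the hit rate;
- **pose_eval** — alpha-carbon Kabsch superposition and symmetry-aware
  ligand heavy-atom RMSD (minimum over bond-graph automorphisms), with
  successful (<2 Å) / acceptable (2–3 Å) / unsuccessful (>3 Å) summaries;
- **synthetic** — fixture generators: toy helix complexes with exactly
  recoverable planted contacts, labeled profile tables with planted class
  signal, and pose sets at known RMSD.

## CLI

All functionality is exposed through the `gifp` command; every run writes a
resolved-config JSON next to its outputs.

```sh
gifp read --pdb complex.pdb --ligand auto --chain auto --bw-map bw.tsv --out complex.json
gifp contacts --complex complex.json --score-cutoff 0.0 --out contacts.tsv
gifp fingerprint --contacts-dir contacts/ --score-cutoff 0.5 --state active \
    --threshold auto --out fp.json
gifp features --complex-dir complexes/ --min-count 10 --out features.csv
gifp train --features features.csv --seed 17 --out model/
gifp predict --model model/ --features new.csv --majority-by model_id,ligand_id \
    --merged --out preds.csv
gifp evaluate --preds preds.csv --merged --out metrics.json
gifp rmsd --reference reference.json --poses poses.tsv --top 5 --out rmsd.tsv
gifp synth complex|profiles|poses --spec spec.json --seed 7 --out out/
gifp screen --features poses.csv --model model/ --group-by model_id,ligand_id \
    --out screen.csv
```

The BW annotation table is a 4-column TSV
(`chain  author_number  insertion_code  bw_position`) with `.` for an empty
insertion code and `-` for unmapped loop/terminal residues.

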