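# peptaibiome

Tools for characterising the **peptaibiome** — the full complement of
peptaibols a fungal strain produces — from HPLC-ESI-MS data, plus
conformational-ensemble statistics for peptaibol backbones.

Peptaibols are linear non-ribosomal peptides (here: 19 residues) with an
acetylated N-terminus, a C-terminal 1,2-amino alcohol (leucinol, pheol, ...)
and a high content of α-aminoisobutyric acid (Aib). On a unit-resolution ion
trap they appear as sodiated adducts [M+Na]⁺ and [M+2Na]²⁺ and fragment into
acetyl-capped b-ions and amino-alcohol y-ions:

    bₙ = Σ residues(1..n) + mAc + mH⁺          (acylium)
    yₖ = Σ residues(n−k+1..n) + mH₂O + mH⁺     (alcohol terminus already reduced)
    bₙ₋ₖ + yₖ − M = 2 mH⁺                      (complementarity)

The package covers the full workflow:

* **chem** — residue library (20 standard residues + Aib, Iva, amino
  alcohols, isobaric class tokens Lxx/Vxx/Lxxol), neutral masses, adduct m/z
  and fragment ladders.
* **sequencer** — de novo assembly from peak lists: adduct deconvolution,
  b-ladder walking with composite jumps (the 213.11 Da Gln-Aib block),
  y7-family resolution (Lxx/Vxx at 16, Gln/Glu at 18), Aib-Pro-Vxx-Aib motif
  fill for the b13/b14 gap, and mass-closure validation.
* **annotate** — comparison against a known-peptaibol database at
  isobaric-class resolution (identical / positional isomer / exchange lists
  [X]ⁱ→[Y]ⁱ) and elution-order nomenclature (Roman numerals, a/b letters).
* **quant** — proportional calibration against an alamethicin-type external
  standard, relative composition, and the 17–20-residue accuracy flag.
* **conformer** — backbone dihedrals, per-residue Ramachandran free-energy
  surfaces (−RT ln P/Pmax), helix-region classification, backbone H-bond
  detection with turn classes (γ, 3₁₀, α), RMSD-to-average, radius of
  gyration and 2D free-energy landscapes.
* **simulate** — seeded generators for instrument-like peak lists and
  designed helix ensembles, so every stage is testable without instrument
  files.

The packaged fixtures carry the 30 study compounds (19 from a *Trichoderma
gamsii* run, 11 Koningiopsins from a *T. koningiopsis* run) and the
known-peptaibol comparison database.

## Worked example

Simulate the spectrum of trikoningin KA V and sequence it back:

```sh
peptaibiome mass "Ac-Aib-Gly-Ala-Aib-Ile-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Leuol"
```

    M        1889.1350
    [M+Na]+  1912.1242
    [M+2Na]2+ 967.5567
    b12      1122.6517
    y7       768.4978

The neutral monoisotopic mass is 1889.135 Da; b12 (1122.65) and y7 (768.50)
are the two characteristic fragments that identify the compound family on the
chromatogram.

```sh
peptaibiome simulate "Ac-Aib-Gly-Ala-Aib-Ile-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Leuol" \
    --seed 5 --out tkv.csv
peptaibiome sequence tkv.csv
```

    1   Aib   ladder
    2   Gly   ladder
    ...
    13  Pro   motif
    14  Vxx   motif
    15  Aib   motif
    16  Lxx   ladder
    ...
    # M_obs 1889.095 residual -0.040 (complete)

Positions 13–15 carry `motif` provenance: the Aib12–Pro13 bond suppresses
b13/b14, so these residues are predicted from the conserved Aib-Pro-Vxx-Aib
turn motif. All Leu/Ile and Val/Iva calls are class tokens (Lxx, Vxx) —
unit-resolution MS cannot discriminate isobaric members.

```sh
peptaibiome annotate "Ac-Aib-Ala-Ala-Aib-Vxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol"
```

    # new: True
    Trichorzianin TAP-14b  exchanges  1  [Pheol]^19->[Lxxol]^19

i.e. this Koningiopsin differs from trichorzianin TAP-14b only by the
C-terminal alcohol exchange — the hallmark of the Koningiopsin group.

`peptaibiome run` chains the stages (assemble → annotate → name → quantify)
over a directory of peak-list CSVs and writes a study-table-style TSV report.

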