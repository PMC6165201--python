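# Methods

This note documents the models, conventions and design choices behind the
package, and what its synthetic benchmarks do and do not demonstrate.

## Mass chemistry

Residue masses are residue (amino acid − H₂O) masses computed from elemental
compositions with monoisotopic atomic masses H 1.007825, C 12.0, N
14.003074, O 15.994915, S 31.972071, Na 22.989770 Da (electron 0.000549,
proton 1.007276); average masses use the IUPAC conventional atomic weights.
Sodiated adducts use the Na⁺ cation mass (atomic Na minus one electron),
giving [M+Na]⁺ = M + 22.98922 and [M+2Na]²⁺ = (M + 45.97844)/2.

C-terminal 1,2-amino alcohols (leucinol etc.) are stored with the
reduced-carboxyl composition (parent residue − O + 2H, a −13.979 Da shift),
so all downstream sums — neutral mass (Σ residues + H₂O + acetyl), b-ions
(Σ prefix + acetyl + proton) and y-ions (Σ suffix + H₂O + proton) — need no
special-casing of the terminus. Isobaric class tokens (Lxx = Leu/Ile,
Vxx = Val/Iva, Lxxol = Leuol/Ileol) are first-class sequence symbols: class
members share an elemental composition, so class masses are well defined.

Observed ion-trap masses in the packaged tables are unit-resolution values
that mix monoisotopic and isotope-apex readings (nominally identical
compounds print masses differing by up to ~1 Da). Theoretical-vs-printed
comparisons therefore use a ±1.0 Da window in general and ±0.25 Da for the
specific anchor values (b12 and M of trikoningin KA V, the four y7
precursors) that were verified to that precision.

## De novo sequencing model

The assembler targets the acetyl-capped, amino-alcohol 19-residue peptaibol
scaffold; other scaffolds are out of scope.

* **Adduct deconvolution.** Neutral M is taken from [M+Na]⁺; a co-observed
  [M+2Na]²⁺ acts as a cross-check, and disagreement beyond 2× the matching
  tolerance is an error rather than an average — a wrong precursor poisons
  every downstream stage.
* **Matching tolerance.** Default 0.6 Da, a unit-resolution ion-trap figure.
  The Gln/Glu decision on the y7 family is nearest-variant assignment, i.e.
  an effective 0.5 Da boundary on a ~1 Da separation.
* **Sequencing alphabet.** Ladder differences are matched against the
  residues that occur in peptaibols (standard minus Lys, Arg, His, Cys, Met,
  Tyr, plus Aib and the classes). Lysine sits 0.036 Da from glutamine, far
  below unit resolution, and basic residues do not occur in peptaibols, so
  admitting them would only inject unresolvable ambiguity. The full library
  can be passed explicitly.
* **b1 absence and composite jumps.** The single-residue acylium is rarely
  observed, so the first ladder peak may be any bₙ with n ≤ 3, expanded by
  composite enumeration. Two-residue composites are enumerated exactly;
  larger gaps are left unresolved rather than explored combinatorially. The
  213.11 Da jump (stable Gln–Aib bond) expands as Gln-then-Aib. Exactly
  isobaric head pairs ({Aib,Gly} vs {Ala,Ala} at 142.074 Da) are broken by
  an Aib-first prior: peptaibols begin Ac-Aib.
* **Scaffold anchoring.** With M and the y7 family known, the expected
  b15–b18 follow from the suffix composition; observed peaks matching them
  anchor the ladder tail across the b13/b14 gap, which is then bridged by
  the conserved Aib-Pro-Vxx-Aib motif (positions 13–15, provenance
  `motif`; an observed call is never overwritten and a clash is an error).
  Position 17 is fixed as Gln (invariant across the scaffold) and the
  terminus as Lxxol, both with provenance `closure`.
* **Candidate ranking.** Complete-closure candidates first, then fewer
  composite jumps, smaller |closure residual|, preferred branch choices, and
  finally the token string — the last step guaranteeing determinism under
  peak-order permutation.
* **Isobaric honesty.** Output uses only class tokens for Leu/Ile, Val/Iva
  and the alcohol pair; the instrument cannot tell members apart and the
  assembler never pretends otherwise.

## Annotation and nomenclature

Database comparison runs at isobaric-class resolution (a strict mode
exists but is off by default, since published peptaibol tables themselves
annotate across isobaric members). Relations are `identical_by_class`,
`positional_isomer` (equal class multiset, different order) or an exchange
list [X]ⁱ→[Y]ⁱ; candidates rank by relation class, exchange count, then
name. The packaged database reconstructs the trikoningin / tricholongin /
trichostrigocin / trichorzianin comparison sequences from their reported
residue exchanges; it is a test fixture, not a mirror of any external
resource. Where the source tables disagree with themselves (a handful of
rows), the packaged expectation fixture stores the reading consistent with
the majority of rows, marked `[corrected]`.

Naming follows elution order: compounds sorted by retention time get Roman
numerals; a compound joins the previous compound's cluster (sharing its
numeral, with letters a, b, …) when it elutes within `cluster_window`
(default 1.2 min) *and* its y7 mass is larger by more than the family
tolerance (0.5 Da). The ascending-y7 condition both assigns letters and
prevents chains of co-eluting compounds from collapsing into one cluster.
This rule reproduces the complete 19-label series of the first study table.
It cannot reproduce every manual labelling: in the second table one printed
a/b pair has the *higher*-y7 member eluting first, which contradicts the
ascending-letter convention itself — no deterministic rule satisfies both
tables, and the window stays exposed as a parameter.

## Quantitation

A proportional (through-origin) model maps peak area to concentration:
f = Σac/Σa², fitted on external-standard points. One response factor serves
all compounds, because a single external standard cannot yield
compound-specific factors; compounds outside the 17–20-residue window (the
length regime of an alamethicin-type standard) are flagged `low_accuracy`
rather than silently reported. The packaged tables carry relative areas
only, so absolute contents of the original extracts are not reproduced —
only composition statistics (e.g. the two dominant compounds of the first
run together carrying 51.3 % of the pool).

## Conformational statistics

Free energies use ΔG = −RT ln(P/P_max) over occupancy histograms
(R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, default T = 300 K, default 72×72 bins over
[−180°, 180°]²). Empty bins are masked, not set to infinity; the occupied
minimum is exactly 0 by construction.

Ramachandran regions are rectangular boxes: α_R φ∈[−100,−30], ψ∈[−80,−5];
3₁₀_R φ∈[−80,−40], ψ∈[−45,−10] (a subset of α, tested first); β
φ∈[−180,−90], ψ∈[90,180]; PPII φ∈[−90,−20], ψ∈[120,180]; left-handed
regions are the point reflections. Published region names come without
boundaries; these boxes are declared constants.

Backbone H-bonds: acceptor O(i) … donor N(j) with heavy-atom distance
≤ 3.0 Å and N–H…O angle ≥ 135°; the amide H is reconstructed at 1.01 Å
opposite the C(i−1)/CA bisector when absent; proline and the N-terminal
residue never donate; |j−i| < 2 pairs are excluded as covalent-neighbour
artefacts. Turn classes follow j−i (2: γ, 3: 3₁₀, 4: α; anything else
`other`, including long-range contacts). The 3.0 Å / 135° criteria are the
common trajectory-analysis defaults and are consistent with mean H-bond
distances ≈ 2.9 Å in this regime.

RMSD-to-average superposes frames by Kabsch rotation onto their coordinate
average (seeded by the first frame, average recomputed once), selection
N/CA/C. Radius of gyration is the RMS distance of selected atoms from their
centre of mass (unit weights by default — the selection, not the masses,
carries the physics).

## Synthetic data: what it shows and what it does not

The spectrum simulator emits the adduct pair, the b-series minus a dropout
set (default {b1, b13, b14}, mirroring what the instrument actually loses),
y7 and optional MS2 sub-ions, with Gaussian centroid noise (default σ =
0.05 Da, a realistic ion-trap centroid jitter) and seeded log-uniform
intensities. Round-trip recovery of all 30 packaged sequences under these
conditions shows the assembler is correct and robust to that noise model; it
does not show robustness to chimeric spectra, intensity-dependent effects or
systematic calibration error, none of which are simulated.

The helix generator builds N/CA/C/O backbones by natural-extension placement
from canonical dihedrals (α: ∓57/∓47; 3₁₀: ∓49/∓26; sign by handedness),
ω = 180°, bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å and
bond angles N-CA-C 110.0°, CA-C-N 117.2°, C-N-CA 121.7°, CA-C-O 120.5° —
standard values chosen so that ideal helices exhibit their textbook H-bonds
(α i+4→i at 3.00 Å, 3₁₀ i+3→i at 2.77 Å). Per-frame Gaussian jitter on
φ/ψ provides ensembles with tunable disorder. These ideal ensembles verify
the classifiers and estimators; they are not substitutes for real
trajectory ensembles, whose statistics (H-bond fractions, RMSD/RoG
landscapes) depend on force field and sampling and are not reproduced here.

## Known limitations

* Scaffolds other than acetyl-capped 19-residue amino-alcohol peptaibols are
  not assembled (the chemistry layer itself is length-agnostic).
* Charge states above 2+ and adducts other than H⁺/Na⁺ are unsupported, as
  is isotope-pattern simulation.
* Manual a/b letterings that contradict the ascending-y7 convention cannot
  be reproduced (see Annotation above).
* Ensemble readers expect standard atom naming (N, CA, C, O, H) in
  multi-model PDB files.
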