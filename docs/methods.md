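# Methods

## Scope and model

The package predicts qualitative physicochemical behaviour of ionic
liquids (viscosity η, n-octanol–water partition coefficient K_OW, water
solubility S, enthalpy of fusion ΔH_F) from structure alone, by placing an
IL on a fixed two-component chemical-space map and reading trend rules off
its coordinates and cluster. Quantitative modelling is provided only for
ΔH_F, as a QSPR-MLR workflow validated by planted-model recovery. The
underlying assumption throughout is that for these four properties the
cation and anion contributions are additive and dominated by ion *size*
and composition, so that 0D/1D constitutional descriptors — which ignore
geometry, conformation and explicit intermolecular forces (hydrogen
bonding in particular) — carry enough signal for qualitative ranking.

## Constitutional descriptor block

41 descriptors per ion, fixed registry order, versioned
(`ilpc-registry-41-v1`); the IL vector concatenates cation (`^C`) and
anion (`^A`) blocks to 82 slots. Conventions:

- Implicit hydrogens are always materialized into nH, nAT, nBT, MW and the
  weighted sums; every hydrogen carries exactly one bond, so
  nAT = nSK + nH and nBT = nBO + nH hold identically.
- SCBO sums bond orders over the H-depleted graph with aromatic = 1.5.
- A rotatable bond (RBN) is any non-ring, non-aromatic single bond whose
  two heavy endpoints each have heavy-degree ≥ 2. This purely topological
  rule is applied uniformly — no amide or other functional-group
  exclusions — because it is deterministic and auditable; it therefore
  counts slightly more bonds as rotatable than pharmacophore-oriented
  definitions.
- Carbon hybridization from bond orders only: any triple bond or two
  double bonds → sp; one double bond or any aromatic bond → sp²;
  otherwise sp³.
- The weighted sums Se/Sp/Si/Sv divide each atom's Sanderson
  electronegativity / polarizability / first ionization potential / van der
  Waals volume by the carbon value; the element table is shipped with the
  package (masses: IUPAC 2021; EN/polarizability/IP: standard descriptor
  handbooks; vdW volumes from Bondi-type radii), versioned, and covers
  H, B, C, N, O, F, P, S, Cl, Br, I. Formal charge never changes a lookup:
  these are composition scales.
- Registry membership: the registry keeps the cumulative van der Waals sum
  Sv but not its mean Mv (AMW already plays the mean-size role); the exact
  41-name membership is a documented, versioned choice and is the one
  degree of freedom a different registry version may revisit.

Each ion is parsed with RDKit (SMILES or V2000 SDF) and frozen into a
plain connected graph record; multi-fragment inputs and impossible
valences are errors, never silently repaired. All descriptors are pure
functions of that record, hence invariant to atom ordering in the input.

## Chemical-space map

Correlation-matrix PCA: columns are autoscaled to mean 0 and sample sd 1
(ddof = 1), so the eigenvalues of the fitted covariance sum to the number
of retained columns and "explained fraction" is eigenvalue / #retained.
Columns whose sd is below 1e-12 relative to their magnitude are constant
in the reference set (e.g. halogen counts of cations that never carry
halogens); they are dropped from the map and reported by name.
Autoscaling rather than range scaling was chosen because the descriptor
mix spans incommensurate units (mass vs counts) and loading/score
correlations then obey the exact identity r = loading·√λ, which the
implementation checks internally at 1e-8.

Numerical conventions: components come from `numpy.linalg.eigh` of the
sample covariance of the scaled matrix, ordered by non-increasing
eigenvalue; each loading column's largest-magnitude entry is made
positive; then PC1 is flipped if cation molecular weight (MW^C) correlates
negatively with it and PC2 likewise against anion molecular weight (MW^A).
The two orientation keys differ because the second axis of the map is
anion-driven; with both keys applied, PC1 grows with overall ion size and
PC2 with anion heavy-atom size, which is the orientation the trend rules
assume. Projection of a query vector is (x − mean)/sd · loadings; a
training row reprojects onto its stored score to 1e-8.

Loading interpretation uses the strict rule |r| > threshold (default 0.7):
a correlation exactly at the threshold is not significant.

## Clustering

Ward's minimum-variance method on Euclidean distances, run in the
retained-score space (2-D by default) because that is the space in which
the reference map's clusters are defined and in which queries are placed.
The linkage is computed by the Lance–Williams recurrence on squared
distances with an explicit deterministic tie-break (the merge whose
combined member set sorts first); heights follow the
sqrt(2·ΔESS) convention, identical to SciPy's, and SciPy plus an
exhaustive from-scratch ESS oracle serve as cross-checks in the tests.
The dendrogram is cut at k = 6 (configurable) and letters are assigned by
geometry: the k//2 centroids with the smaller PC1 take A, B, C in
ascending PC2; the larger-PC1 half takes F for its lowest-PC2 centroid and
D, E ascending above it. A rank split was preferred over a PC1-sign split
because the small-cation/TFSI cluster can sit marginally right of zero.
New ILs are assigned to the Euclidean-nearest centroid; exact ties go to
the alphabetically first label and are flagged.

## Property overlays and trend rules

Measured property values are standardized per property (z-scores,
population sd). Viscosity, K_OW and solubility are log-transformed first —
their natural scales are heavy-tailed over orders of magnitude — while
ΔH_F stays on its kJ/mol scale. The range scale for map painting uses five
bins with edges z = −1.5, −0.5, 0.5, 1.5 (configurable); binning is
half-open with a boundary value belonging to the upper bin and the outer
bins unbounded.

Trend scores are signed linear reads of the map coordinates with unit
default weights: T_visc = +PC1 − PC2, T_Kow = +PC1, T_sol = −PC1 + PC2,
T_ΔHF = +PC2. Only the signs (and PC2's dominance for ΔH_F) are fixed by
the trend analysis; the unit magnitudes are configuration. Ordinal levels
come from the query's trend-score percentile against the training ILs with
cuts at 33⅓ % and 66⅔ %. Two qualifications are attached automatically:
the ΔH_F answer carries a reduced-confidence note plus the cluster
heuristic (C high-prone, A and F low-prone, B/D/E uncertain), and
solubility answers for large-cation ILs (PC1 > 0) are flagged because the
anion-size term of the solubility trend reverses in that region.

## QSPR workflow

- **Split:** records sorted by response; every third (2nd, 5th, …) goes to
  validation, except that the largest response always stays in training —
  so both extremes are calibrated and the external set interpolates.
- **MLR:** ordinary least squares with intercept; singular designs are
  rejected with the collinear pair named. R² and RMSE on training data.
- **Q²_LOO:** exact hat-matrix shortcut (LOO residual = e_i/(1 − h_ii));
  an explicit n-refit path is kept alongside and the two agree to 1e-10.
- **Q²_ext** = 1 − Σ(ŷ − y)² / Σ(y − ȳ_train)², with RMSE_ext.
- **GA selection:** fixed-size subsets; rank-based parent pool (top half),
  uniform subset crossover (rate 0.8), point mutation (rate 0.05),
  elitism, population 50 × 100 generations by default; fitness is Q²_LOO
  of the subset's MLR; fully reproducible from the seed. Model sizes above
  n/5 are rejected (parsimony). An exhaustive-enumeration selector is
  provided for pools up to ~12 and is the oracle the GA is tested against.
- **Applicability domain:** leverage-only, h = x(XᵀX)⁻¹xᵀ on
  intercept-augmented rows, warning threshold h\* = 3(p+1)/n; standardized
  residuals (±3 sd rule) are reported when observations accompany queries,
  giving Williams-plot data.

The reference ΔH_F equation itself is not reproduced: its training data
and coefficients are not available. The workflow is instead validated by
exact recovery of planted linear models (R² = Q²_LOO = Q²_ext = 1 in the
noiseless case) and by the GA-vs-enumeration and leverage identities.

## Synthetic reference generator

The generator (`ilpc.fixtures`) emulates the composition of a realistic
reference collection: six cation families (1-alkyl-3-methylimidazolium,
alkyltributylammonium, alkyltrihexylphosphonium, N-alkylpyridinium,
N-alkyl-N-methylpyrrolidinium, alkyldimethylsulfonium) with alkyl chains
of 2–8 carbons, paired with four anion classes. The pairing follows real
IL chemistry rather than a full factorial — small-cation families carry
halide, fluoroborate-like and TFSI-like anions; amino-acid anions appear
with the large ammonium/phosphonium cations, phosphonium taking the larger
amino acids — which is also what produces the map's six-cluster anatomy.
Property values are generated from latent size coordinates (z-scored
cation and anion molecular weights) with the trend structure the map
encodes: log η = 4.0 + 1.2·(z_cat + anion offset, TFSI-like −1.0 …
halide +0.6); log K_OW = z_total; log S = 4.0 + 1.2·(−z_cat + 0.6·z_an)
(normalized); ΔH_F = 25 + 8·z_an kJ/mol; Gaussian noise of sd 0.3 on the
standardized latent scale. Defaults give 60 ILs (10 per family), a size at
which the full pipeline runs in well under a second.

What the generator does **not** emulate: real descriptor–property
nonlinearities, hydrogen-bond-driven viscosity anomalies, measurement
heterogeneity across laboratories, and the long tail of rare anion
chemistries. Passing tests therefore demonstrate that the machinery
recovers structure it is pointed at — not that the qualitative predictions
are accurate for laboratory ILs; that depends on the reference data a user
fits the map to.

There is also a planted-covariance matrix generator for PCA/QSPR unit
tests: exactly orthogonal zero-mean score columns scaled to requested
variances times orthonormal loadings, so the sample-covariance eigenvalue
fractions equal the requested split exactly at zero noise.

## Known limitations

- Cluster letters are a geometric convention applied to whatever six
  clusters Ward finds; when the cut does not land on the six intended
  structural cells (possible at unlucky seeds/noise levels), a letter can
  attach to a cluster whose chemistry differs from the canonical A–F
  description, and the cluster-based ΔH_F/viscosity rationale inherits
  that mismatch. The trend-score levels are unaffected.
- The map explains ~67 % of the synthetic set's variance in two
  components; reference sets with stronger internal correlation will score
  higher, but the two-component choice is a presentation criterion, not an
  optimality claim.
- Element coverage is the eleven elements above; exotic ions (selenium,
  metals) are rejected with a clear error rather than guessed at.
- All qualitative outputs are relative to the fitted reference set; they
  are percentile statements, not absolute property ranges.
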