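# ilpc — ionic-liquid physicochemical predictor

`ilpc` is a pre-synthesis screening tool for ionic liquids (ILs): salts
defined by one cation and one anion, liquid at or near ambient temperature.
Given nothing but the two ions' structures (SMILES or SDF), it answers the
questions an IL designer asks before committing to a synthesis: roughly how
viscous will this liquid be, how hydrophobic (n-octanol–water partition
coefficient K_OW), how water-soluble, and how large an enthalpy of fusion
ΔH_F? The answers are qualitative — low / medium / high against a reference
collection — which is exactly the resolution available before any
experiment.

## How it works

1. **Constitutional descriptors.** Each ion is reduced to 41 zero-/one-
   dimensional descriptors computable from composition and connectivity
   alone: molecular weight MW and mean atomic weight AMW; the carbon-scaled
   cumulative Sanderson electronegativity, polarizability, first ionization
   potential and van der Waals volume (Se, Sp, Si, Sv) and their means;
   atom, bond, multiple-bond and rotatable-bond counts (nAT, nSK, nBT, nBO,
   SCBO, RBN, RBF, …); element counts and percentages; and carbon sp³/sp²/sp
   hybridization counts. The cation block and anion block concatenate into
   an 82-slot IL vector (names suffixed `^C` / `^A`).
2. **Chemical-space map.** The reference set's 82-column matrix is
   autoscaled (constant columns dropped and reported) and eigendecomposed;
   the first two principal components define a fixed linear map. PC1 is
   oriented to grow with overall ion size, PC2 with anion (heavy-atom)
   size. A variable is read as shaping a component when |r(variable,
   score)| > 0.7 (Malinowski's rule, strict).
3. **Structural clusters.** Ward/Euclidean hierarchical clustering of the
   training scores, cut at k = 6, gives clusters lettered A–F by map
   geometry: small-ion side A (halides, low PC2), B, C (TFSI-like, high
   PC2); large-ion side F (halides), D, E (large amino-acid anions).
4. **Trend rules.** A query IL is projected onto the map and scored by
   T_visc = +PC1 − PC2, T_Kow = +PC1, T_sol = −PC1 + PC2, T_ΔHF = +PC2;
   each score becomes low/medium/high by percentile against the training
   ILs, with cluster-based rationale (e.g. TFSI cluster C → lowest
   viscosities, high-ΔH_F-prone).
5. **QSPR workflow.** For quantitative ΔH_F modelling the package provides
   the standard OECD-style chain: deterministic train/validation split,
   genetic-algorithm selection of a small descriptor subset, multiple
   linear regression, R²/Q²_LOO/Q²_ext/RMSE statistics, and a
   leverage-based applicability domain with h\* = 3(p+1)/n.

The original reference collection is not redistributable, so the package
ships a deterministic generator (`ilpc.fixtures`) that emulates its
composition: six cation families × four anion classes with realistic
family–anion pairings and property values following the map's trend
structure.

## Worked example

```sh
ilpc fixtures --out fx --seed 7                     # synthetic reference set
ilpc fit --in fx/ils.csv --prop fx/properties.csv --out model.json
# fitted 60 ILs; explained 37.79% + 29.56% = 67.35%; bundle -> model.json

cat > new.csv <<EOF
il_id,cation_smiles,anion_smiles
bmim-ntf2,CCCCn1cc[n+](C)c1,C(F)(F)(F)S(=O)(=O)[N-]S(=O)(=O)C(F)(F)F
thtdp-cl,CCCCCCCCCCCCCC[P+](CCCCCC)(CCCCCC)CCCCCC,[Cl-]
EOF
ilpc predict --model model.json --in new.csv --out pred.csv --plot map.svg
```

`pred.csv`:

```text
il_id,PC1,PC2,cluster,visc_level,kow_level,sol_level,dhf_level,flags,error
bmim-ntf2,-0.92,9.24,C,low,medium,high,high,,
thtdp-cl,6.14,-8.78,F,high,high,low,low,solubility-anion-trend-reverses-for-large-cations,
```

Read: 1-butyl-3-methylimidazolium bis(trifluoromethylsulfonyl)imide lands
in cluster C (small cation, TFSI anion, high PC2) — expected low viscosity
but a high enthalpy of fusion; trihexyl(tetradecyl)phosphonium chloride
lands in cluster F (very large cation, halide) — viscous, hydrophobic,
poorly water-soluble, low ΔH_F, with a caveat that the anion-size
solubility trend reverses for large-cation ILs. The percentages printed by
`fit` are the variance fractions the two map components preserve from the
66 retained (non-constant) descriptor columns.

The same operations are available from Python (`ilpc.build_reference_model`,
`ilpc.predict_new`, `ilpc.ga_select`, …); the CLI is a thin wrapper.

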