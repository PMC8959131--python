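# Methods

## Model and workflow

`gaqsar` builds ligand-based QSAR models of the form

    pKi = b0 + Σ_j b_j · d_j(molecule)

where pKi = −log10(Ki [M]) and the d_j are molecular descriptors drawn from a
small grammar (below). The workflow is the classical two-stage selection
pipeline used by tools such as QSARINS:

1. **Curation.** Records with non-numeric ("ambiguous") Ki, unparseable
   structures, or metal-based inhibitors are excluded with a recorded reason;
   salt counterions are stripped to the largest organic fragment; duplicates
   (identical canonical structure after salt stripping) are collapsed,
   first-seen wins. Ki arrives in nM; pKi = 9 − log10(Ki[nM]), i.e. the
   transform is taken on the molar scale — the only reading under which a
   0.146 nM inhibitor has pKi 9.84.
2. **Featurization** over the descriptor grammar (~460 candidate columns with
   the default k ≤ 7 pair-frequency pool).
3. **Objective feature selection (OFS)** — response-blind pruning of
   constant columns, near-constant columns (≥ 95 % identical values or
   variance < 1e-8) and inter-correlated columns (|Pearson r| > 0.90,
   scanning alphabetically so the first member of a correlated pair
   survives; fully deterministic removal log).
4. **Random 80/20 split** into training and external sets (floor convention:
   197 → 157/40), seeded.
5. **Subjective feature selection** by GA-MLR: fixed-size descriptor subsets
   are evolved with fitness Q²LOO of the OLS fit on the training set.
6. **Validation battery** and Williams applicability domain.
7. **Virtual screening**: the fitted model predicts pKi for a library,
   converts to Ki = 10^(9−pKi) nM, attaches leverage/in-domain flags, and
   ranks (ties broken by compound id; out-of-domain compounds are flagged,
   never dropped).

## Descriptor grammar

* **Pair frequencies** `f<A><B><k>B`: the number of ordered atom pairs
  (a ∈ A, b ∈ B, a ≠ b) whose shortest-path distance on the heavy-atom graph
  is exactly k bonds. Counting ordered pairs makes the definition symmetric
  in the two classes — `fringNaroC5B` ≡ `faroCringN5B` — which is asserted by
  property tests. Disconnected pairs contribute zero. Hydrogens are excluded
  from the graph and from all atom classes, so counts do not depend on
  protonation drawing conventions.
* **Atom classes** are pure predicates on perceived heavy atoms: `ringN`,
  `aroN`, `aroC`, `ringC`, `notringC`, `sp2C`, `sp3C`, `sp2O`, `sp3O`, `acc`
  (any O, plus N that is neither quaternary/cationic nor a pyrrole-type
  aromatic N donating its lone pair into the ring), `N`, `O`. Oxygen
  hybridization follows the sigma/pi bonding pattern (a double or aromatic
  bond ⇒ sp2, otherwise sp3), so a carboxyl group contributes one sp2 O and
  one sp3 O and a phenol O is sp3; this matches the descriptor-naming
  convention rather than conjugation-aware perception, which would label all
  of these sp2.
* **Charge-bin counts** (`N_hy1`): atoms of a class with Gasteiger partial
  charge strictly inside an interval, default (−0.199, −0.100) e. The strict
  open interval follows the printed definition; a config switch
  (`inclusive=True`) turns it into a closed range for the paraphrased
  reading. `N_MSA1` is exposed as an alias of the same computation: the two
  published names carry verbally identical definitions.
* **Surface descriptors**: Shrake–Rupley areas on a single embedded
  conformer with Bondi van der Waals radii. Probe 0.0 Å defines the
  "molecular surface area" (MSA), probe 1.4 Å the solvent-accessible surface
  (SASA), `rsa = MSA/SASA`. Per-class areas (`notringC_MSA`) sum probe-0
  atomic areas with each hydrogen's area folded into its parent heavy atom.

## Numerical choices

* **Gasteiger charges**: 8 damped iterations (damping ½^k), computed with
  RDKit; charges conserve the net formal charge to 1e-3 e (checked on every
  molecule).
* **Conformers**: one ETKDG embedding per molecule, seeded, with explicit
  hydrogens and no force-field refinement — refinement would buy little for
  an area *ratio* and would cost exact reproducibility. Absolute rsa values
  therefore differ from pipelines that minimize and align conformers; the
  fixture suite asserts only the geometry-level contracts (closed-form
  spheres, MSA ≤ SASA, rsa in a plausible 0.4–0.9 band for multi-atom
  organics).
* **Surface sampling**: deterministic Fibonacci (golden-angle) sphere point
  sets, 960 points per atom by default; totals agree with a 9600-point
  computation within 2 % on the fixture set. A sample point lying exactly on
  a coincident sphere's boundary is credited to the lower-indexed atom so
  degenerate overlaps count once.
* **OLS** is solved by QR on the intercept-augmented design; rank deficiency
  is an error that names the collinear columns, except identically-zero
  columns, which receive coefficient 0 (they carry no information and arise
  naturally from all-zero descriptor selections).
* **Q²LOO** uses the closed-form leave-one-out residual e_i/(1−h_ii); tests
  verify exact (1e-10) agreement with an explicit n-refit loop. Leverage 1
  points raise.
* **Q²LMO**: 30 % left out, 1000 random iterations, seeded; each iteration
  scores held-out predictions against the held-out TSS about the training
  subset's mean.
* **Y-scrambling**: 1000 permutations of the response on the fixed
  descriptor subset, reporting mean R² and mean Q²LOO. Both statistics are
  conventional (values near 0 for a sound model); a model's R² should exceed
  the scrambled mean by a wide margin (> 0.4 on the planted bench).
* **K correlation indices**: Todeschini's K over the eigenvalues of the
  correlation matrix, on the descriptor block (Kxx) and the block plus
  response; ΔK = Kxy − Kxx with ΔK ≥ 0.05 as the acceptance cutoff.
* **Williams domain**: leverage h = a(AᵀA)⁻¹aᵀ with intercept column,
  warning leverage h* = 3(p+1)/n, residual band ±3 standardized units (the
  standard convention for the plot).
* **Thresholds**: R²tr ≥ 0.6, Q²LOO ≥ 0.5, Q²LMO ≥ 0.6, R²ex ≥ 0.6,
  CCC ≥ 0.80, Q²F1–F3 ≥ 0.60, r²m(avg) ≥ 0.5, ΔK ≥ 0.05,
  0.9 ≤ k, k′ ≤ 1.1, plus the derived conditions R² > Q², RMSEtr < RMSEcv,
  |r²o − r′²o| < 0.3 and the Golbraikh–Tropsha through-origin ratio test.

## Genetic algorithm

Chromosomes are descriptor subsets of fixed size (default 6, matching the
published model's dimensionality). Defaults: population 64, 300 generations,
tournament-of-3 selection, uniform crossover over the parents' union repaired
back to the fixed size, single-gene swap mutation with probability 0.1,
elitism 2, seeded NumPy RNG, and a fitness cache keyed by subset. Fitness is
plain Q²LOO (no size or collinearity penalty — the subset size is fixed).
The best-so-far trace is non-decreasing by construction. An optional
`patience` early stop exists but is off by default: on the planted bench the
full 300 generations are what make the global optimum reliably reachable
(20/20 seeds versus 16/20 with an aggressive early stop).

## Synthetic data: what it emulates, and what it does not

The package is exercised entirely on generated inputs:

* **Fixture molecules** (pyridine, 2-phenylpyridine, nicotinamide, azines,
  alkanes, a salt pair, …) with hand-derived pair-frequency and count values
  asserted exactly, and BFS/closed-form oracles for distances and surfaces.
* **Planted benches**: descriptor-like matrices (two thirds Poisson
  count-like, one third Beta ratio-like columns) with a known sparse affine
  signal. Coefficients are scaled so signal variance ≈ 1, putting the true
  model's R² near 1/(1+σ²) ≈ 0.8 at the default noise σ = 0.5 — the fit
  quality regime of a good kinase QSAR. Half of the non-signal columns are
  decoys correlated ≈ 0.45 with signal columns so subset recovery is
  non-trivial; the cap keeps the true subset identifiable.
* **Emulated modelling set**: 197 records over a combinatorial azine/biaryl
  SMILES family (14 scaffolds × small substituents, ~2100 valid distinct
  structures). pKi is planted as an affine function of six real descriptors
  (fringNaroC5B, N_hy1, faroNsp2O5B, fsp2Oacc6B, faccsp2C4B, faccaroC3B)
  plus Gaussian noise, affinely mapped so the activity extremes sit exactly
  at Ki = 100 000 nM (pKi 4.0) and Ki = 0.146 nM (pKi 9.84) — log-uniform-ish
  in Ki, the natural QSAR assumption when only a range is known. A handful
  of records are replaced by duplicates, an ambiguous-Ki entry, a salt form
  and a Pt complex so the curation filters are exercised end to end.
* **Screening library**: 161 distinct structures from the same family.

What passing these tests shows: the engine computes its descriptors exactly
as defined, the statistics match their definitions to numerical precision,
and the selection/validation/screening machinery behaves correctly when a
sparse linear structure–activity relationship truly exists. What it does not
show: anything about real kinase inhibitors — the synthetic family is far
narrower chemically than a real medicinal-chemistry series, its
descriptor–activity link is linear by construction, and surface descriptors
on single unrefined conformers will not numerically match values derived
from minimized, aligned 3D structures.

## Problem sizes and determinism

Default study sizes are 197 compounds (157/40 split), a ~460-column candidate
pool pruned to ~100 by OFS, six-descriptor models, 1000-iteration LMO and
1000-scramble Y-randomization, and a 161-compound screening library; the
planted-recovery experiment uses 20 GA runs on a 157×50 bench. Every random
stage (split, GA, LMO, scrambling, conformers, generators) takes an explicit
seed, and rerunning a pipeline with the same config reproduces bit-identical
artifacts on one platform. The surface-descriptor stage is off by default in
the pipeline config (`include_surface`) since the planted signal is purely
topological/electrostatic; switching it on adds `rsa` and `notringC_MSA` to
the pool at the cost of one conformer embedding per compound.

## Known limitations

* Gasteiger parameters cover common organic elements only; exotic elements
  raise (by design) rather than receiving guessed electronegativities.
* The acceptor rule is a simple heuristic (amide N counts as an acceptor;
  real H-bond basicity is more graded).
* Pair counting convention (ordered pairs, both role-orderings when classes
  overlap) is one of several defensible readings of "frequency of
  occurrence"; it was chosen for its testable symmetry and is documented at
  the API.
* `q2_lmo` refits from scratch each iteration (no rank-one updates); at the
  default sizes this costs well under a second.
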