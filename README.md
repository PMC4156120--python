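# malustar

Virtual experiments linking apple-tree architecture to light
interception. `malustar` simulates 1–5-year-old apple trees
(*Malus × domestica*) as stochastic functional–structural models,
measures each simulated crown's diffuse-light interception efficiency,
and ranks the influence of architectural traits on it — the *in silico*
screening step behind ideotype definition in fruit-tree breeding, where
field phenotyping of multi-year tree architectures is too slow and
costly.

The pipeline has three stages:

1. **Architecture.** Tree topology grows year by year: terminal-bud
   fates follow a Markov chain over four growth-unit (GU) states
   (long, medium, short, floral), and axillary branching along long and
   medium shoots follows a hidden semi-Markov chain (HSMC) of branching
   zones — latent base, mixed middle, acrotonic tip. Organ geometry
   follows logistic growth laws for individual leaf area
   (LA = f(d)·LA_max·[1 − δ_rk(1 − rk/n_p)]) and internode length
   (IL = IL_min + g(d)·IL_max·c_z), pipe-model diameter accumulation,
   and Euler–Bernoulli branch bending under gravity and phototropism.
2. **Light interception.** STAR = PLA / TLA — the silhouette (projected)
   leaf area, overlaps counted once, over the total leaf area — computed
   per direction by orthographic rasterization and integrated over a
   46-sector equal-area turtle sky with standard-overcast-sky (SOC)
   weights. STAR ∈ [0, 1]; higher means less self-shading.
3. **Sensitivity analysis.** A generalized additive metamodel
   STAR_i = f₀ + Σ_k f_k(X_k,i) + ε_i with penalized-spline smooths
   (no interactions), reporting per-term equivalent degrees of freedom
   (e.d.f.: 1 ≈ linear, 2 ≈ quadratic), F statistics, p-values,
   adjusted R², and centered response curves with confidence bands.

Two experiments are built in: a **geometry** experiment (Latin
hypercube sample over individual leaf area, internode length, top shoot
diameter and branching angle; default 300 trees × 5 years) and a
**topology** experiment (trees initialized from first-year trunk
branching sequences; sylleptic/proleptic branching densities per metre
of trunk as metamodel inputs). The Markov/HSMC parameterization and the
observed trunk sequences of the original field population are not
public; `malustar.synthetic` ships documented toy stand-ins (see
`docs/methods.md` for exactly what they do and do not emulate).

## Worked example

A scaled-down geometry experiment (30 trees, 3 years) from a YAML
config:

```yaml
# demo.yaml
mode: geometry
n_trees: 30
years: 3
seed: 7
out_dir: demo_run
```

```bash
malustar run-experiment --config demo.yaml
malustar report --run-dir demo_run
```

prints (abridged):

```
           tla                star
          mean       std      mean       std
year
1     0.180496  0.099921  0.395991  0.061518
2     0.843272  0.633688  0.333187  0.058156
3     2.544806  2.288042  0.319315  0.059332

gam_geometry.csv:
 year              input      edf          F            p signif   adj_r2
    1          leaf_area 4.099989  93.047863 2.419904e-14    *** 0.963492
    1   internode_length 1.560326  88.256836 4.037746e-14    *** 0.963492
    1 top_shoot_diameter 5.981513   3.172671 1.509598e-02      * 0.963492
    1    branching_angle 0.964448   0.731456 6.761937e-01        0.963492
    2          leaf_area 6.063778  37.742322 1.289389e-10    *** 0.911404
    2   internode_length 0.991542  18.891312 6.421360e-08    *** 0.911404
    2 top_shoot_diameter 0.199947   0.826296 6.000130e-01        0.911404
    2    branching_angle 2.680459   8.987105 2.563582e-05    *** 0.911404
    ...
```

Reading the output: mean total leaf area (TLA, m²) grows each year
while mean STAR falls — more leaves overlap more. In the per-year
additive-model tables, leaf area and internode length carry by far the
largest F (leaf area lowers STAR, internode length raises it — see
`demo_run/curves_geometry.csv` for the response curves), branching
angle has a moderate effect from year 2, and top shoot diameter none
once the trees are branched; the additive terms explain >90 % of the
STAR variation (adjusted R²). The e.d.f. column measures each curve's
non-regularity: ≈1 is a straight line, larger values are wigglier.

Stand-alone STAR for any leaf set (OBJ polygon soup, one face per
leaf):

```bash
malustar gen-fixtures --kind stacked_k --k 4 --out stack.obj
malustar star --leaves stack.obj --n-sectors 46 --resolution 1e-3 --out stack_star.json
# STAR = 0.2802 (TLA 0.0120 m^2)
```

Four identical stacked horizontal leaves occlude each other completely
from the zenith (directional STAR 1/4 = 0.25); the sky-integrated value
is slightly higher because oblique sectors see the stack edge-on.

Other subcommands: `design` (LHS trait designs), `gen-sequences`
(synthetic trunk sequences), `simulate` (single-tree topology → JSON),
`fit-gam` (sensitivity tables from any results CSV). Everything is also
available as a library (`malustar.topology`, `.geometry`, `.light`,
`.experiments`, `.gam`, `.synthetic`, `.io`, `.config`).

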