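# rhizoasm

Community-assembly, co-occurrence-network and diversity analysis for
rhizosphere (and other amplicon-based) microbiome studies, built around a
4-fertilizer-regime × 4-season × 3-replicate factorial design.

Soil microbial communities are structured by a mix of deterministic
processes (environmental selection) and stochastic ones (dispersal, drift).
`rhizoasm` implements the standard null-model toolkit that partitions those
processes from an OTU table and a phylogeny, together with the descriptive
statistics that usually accompany it, and a synthetic-study generator with
*known* assembly regimes so every stage can be validated against ground
truth.

**Who it is for.** Microbial ecologists analysing taxa-by-sample count
tables (16S/ITS OTUs or ASVs) with sample metadata, a rooted phylogeny and
optional function/guild rule files — and anyone who wants a tested,
scriptable implementation of βNTI/RC_bray/pNST process partitioning.

## What it computes

- **Alpha/beta diversity** — richness, Shannon H′ = −Σ pᵢ ln pᵢ,
  bias-corrected Chao1 = S + F₁(F₁−1)/(2(F₂+1)); Bray–Curtis
  BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); PCoA; ANOSIM
  R = (r̄_between − r̄_within)/(n(n−1)/4) with permutation p-values, and
  PERMANOVA; two-way (regime × season) type-II ANOVA with Tukey HSD letter
  displays and a Kolmogorov–Smirnov normality screen.
- **Function/guild profiles** — rule-driven aggregation of taxon abundances
  into ecological functions (FAPROTAX-style multi-assignment) or fungal
  guilds with a pathotroph/symbiotroph/saprotroph trophic rollup; the rule
  database is a user-supplied TSV.
- **Co-occurrence networks** — Spearman correlation networks under a fixed
  |ρ| cutoff (0.88 bacterial / 0.78 fungal presets) or a ρ > 0.6 & p < 0.01
  dialect; random-matrix-theory threshold scan (nearest-neighbour spacing
  Poisson/GOE tests); topology (avgK, avgCC, geodesic distances GD/HD,
  modularity, power-law R²) against 100 degree-preserving rewired
  baselines; Zi–Pi node roles with the keystone rule Zi ≥ 2.5 or Pi ≥ 0.62.
- **Assembly processes** — abundance-weighted βMNTD, βNTI (z-score against
  a 999-draw tip-shuffle null), Raup–Crick on Bray–Curtis (RC_bray), the
  five-process classification (|βNTI| > 2 → homogeneous/variable selection;
  RC_bray beyond ±0.95 → homogenizing dispersal / dispersal limitation;
  otherwise undominated drift), and the phylogenetic normalized
  stochasticity ratio pNST with the 0.5 stochastic/deterministic boundary.
- **Neutral & niche models** — Sloan's neutral community model
  F(p) = 1 − Beta(d; Nmp, Nm(1−p)) fitted for the migration rate m with a
  95 % prediction band, and Levins niche breadth B = 1/ΣPᵢⱼ² with a
  fixed-margin permutation test splitting taxa into generalists,
  specialists and neutral taxa.
- **Synthetic studies** — 48-sample studies on a simulated Yule phylogeny
  with log-normal abundance structure, Brownian (early-burst) niche traits,
  and four assembly scenarios: `neutral`, `dispersal_limited`, `selection`,
  `mixed`, each with per-sample truth labels.

## Worked example

Simulate a dispersal-limited study and partition its assembly processes:

```python
from rhizoasm.simulate import scenario_preset, emit_study
from rhizoasm.assembly import pair_assembly, process_fractions, pnst
from rhizoasm.neutral import ncm_fit

study = emit_study(scenario_preset("dispersal_limited", seed=42))
pairs = pair_assembly(study.table, study.tree, n_null=99, seed=0)
groups = study.metadata.set_index("sample_id")["regime"]
print(process_fractions(pairs, groups).round(1))
```

```
       n_pairs  homogeneous_selection  variable_selection  homogenizing_dispersal  dispersal_limitation  undominated_drift
group
CF          66                    0.0                 0.0                    18.2                  81.8                0.0
CK          66                    0.0                12.1                    16.7                  71.2                0.0
CMF         66                    0.0                 1.5                    16.7                  81.8                0.0
OF          66                    6.1                 6.1                    18.2                  69.7                0.0
```

Dispersal limitation dominates every regime (70–82 % of sample pairs), as
it should for communities assembled from independently perturbed regional
pools — the generator's truth labels say exactly that. The same study reads
as stochastic on the pNST scale and fits the neutral model poorly:

```python
for r in pnst(study.table, study.tree, groups, n_null=99, seed=0):
    print(f"{r.group}: pNST = {r.pnst:.3f} ({r.verdict})")
fit = ncm_fit(study.table)
print(f"NCM: Nm = {fit.Nm:.0f}, m = {fit.m:.3f}, R² = {fit.r_squared:.3f}")
```

```
CF: pNST = 0.914 (stochastic)
CK: pNST = 0.919 (stochastic)
CMF: pNST = 0.928 (stochastic)
OF: pNST = 0.854 (stochastic)
NCM: Nm = 838, m = 0.084, R² = 0.634
```

pNST > 0.5 in every regime (dispersal limitation *is* a stochastic
process), while the apparent migration rate m = 0.084 is far below the
generator's nominal 0.5 — between-cell pool perturbations depress
occurrence frequencies below the neutral expectation.

The same workflow is available from the shell:

```bash
rhizoasm simulate --scenario dispersal_limited --seed 42 --out study/
rhizoasm assembly --table study/table.tsv --metadata study/metadata.tsv \
    --tree study/tree.nwk --n-null 999 --seed 0 --out results/
rhizoasm all --scenario neutral --seed 1 --out run/   # full pipeline
```

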