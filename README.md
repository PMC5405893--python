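# naplines

Tools for studying sensitivity to **nonaccidental properties (NAPs)** —
image relations such as collinearity, parallelism, cotermination,
junction type and curvature sign that survive viewpoint changes and,
under Recognition-By-Components theory, distinguish the volumetric
primitives (geons) that object recognition is built on. `naplines`
implements the minimal version of that question: can NAP sensitivity be
probed with stimuli made of just **two line segments**, with no object
context at all?

The package is aimed at visual psychophysicists and computational
neuroscientists who want a fully scripted, reproducible version of this
paradigm:

1. **Stimulus generation** (`naplines.geometry`) — 13 conditions, each
   reduced to one scalar parameter whose boundary is the nonaccidental
   configuration. A triplet holds the base stimulus at `boundary + δ`,
   its NAP variant at the boundary, and its metric (MP) variant at
   `boundary + 2δ`, so |Δparam(MP)| = |Δparam(NAP)| exactly. Six
   mirror/pose exemplars per condition give 78 triplets, 3° in extent,
   with a 1.5° gap between the segment centers of every base stimulus
   (2.25° in the replication configuration).
2. **Rendering** (`naplines.render`) — white strokes on gray, exact
   distance-field rasterization, PNG I/O.
3. **GaborJet audit** (`naplines.gaborjet`) — a V1-like model (complex
   Gabor magnitudes on a 12×12 jet grid, 5 scales × 8 orientations)
   and cosine similarity, used to check that NAP variants are not
   simply more discriminable than MP variants in low-level terms.
4. **Trial design** (`naplines.experiment`) — the factorial
   odd-one-out table: 78 × 2 (MP/NAP) × 2 (variant or base is the
   target) × 4 (target quadrant) = 1,248 trials, displays at 5°
   eccentricity with ±0.25° / ±5° jitter.
5. **Synthetic observer** (`naplines.observer`) — shifted-lognormal
   reaction times with participant random effects, a per-condition NAP
   advantage, and near-ceiling accuracy (0.90 metric / 0.97 NAP).
6. **Analysis** (`naplines.analysis`, `naplines.calibration`) —
   per-participant median RTs; one-tailed related-samples t-tests per
   condition, Bonferroni-corrected over 13 comparisons
   (t = mean(d)/(sd(d)/√n) on d_p = median_MP,p − median_NAP,p);
   2×2 within-subject interaction F(1, n−1) = t² of the per-participant
   difference of differences; accuracy summaries; and the Pearson
   correlation between per-triplet behavioral (NAP−MP) RT differences
   and GaborJet similarity differences.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from naplines.pipeline import run_pipeline

out = run_pipeline(seed=42, run_audit=True)

print(round(out["audit_fraction_matched"], 3))
for t in out["tests"][:2]:
    print(t.label, round(t.statistic, 2), round(t.p, 4), t.significant_bonferroni)
ia = out["interaction_axis_vs_control"]
print(round(ia.statistic, 2), round(ia.p, 3))
```

prints

```
0.795
alignment 7.34 0.0 True
collinearity_between 2.6 0.0144 False
6.32 0.033
```

Reading the numbers: the GaborJet audit finds 79.5% of triplets
"properly matched" (the NAP variant is at least as similar to the base
as the MP variant, within 0.01 cosine) — the mismatches are confined to
the curvature conditions, where a straight line is genuinely special to
fine V1-like channels. On the simulated observers (generating NAP
advantage 60 ms for most conditions), alignment reaches t(9) = 7.34
(survives Bonferroni at α = .05/13) while collinearity-between at
p = .0144 does not; the curvature-axis vs single-line-control
interaction F(1,9) = 6.32, p = .033 shows the configural curvature
effect exceeding the single-line one, while edges-vs-control stays flat
(F(1,9) = 0.04). Mean accuracies land at 0.893 (metric) and 0.970
(nonaccidental), near the generating probabilities.

The same steps are scriptable from the shell:

```bash
naplines generate --out manifest.csv
naplines audit    --manifest manifest.csv --out audit.csv
naplines trials   --manifest manifest.csv --seed 1 --out trials.csv
naplines simulate --manifest manifest.csv --trials trials.csv --seed 1 --out responses.csv
naplines analyze  --responses responses.csv --audit audit.csv --outdir results/
naplines pipeline --seed 1 --outdir results/   # all of the above at once
```

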