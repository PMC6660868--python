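# ivcsoa — risk-based sanitary inspection scoring

`ivcsoa` implements a risk-based inspection, surveillance and control
(IVC) model for health regulators: instead of visiting every regulated
establishment on a fixed rotation, the regulator scores each establishment's
sanitary risk and inspects the riskiest first. The package is aimed at
analysts in regulatory agencies (food, drugs, medical devices, cosmetics,
blood and tissue banks) and at anyone building composite risk indices from
ordinal inspection data.

## The model

Each establishment *i* is scored on ordinal risk variables (1–5, 5 = highest
risk), assigned from qualitative reference tables (observed condition →
score). Three components are combined:

- **VT_i** — weighted mean of the seven *transversal* variables common to
  all product lines (activity complexity, standards compliance, time since
  last visit, sanitary measures, complaint history, registrations,
  technical responsible);
- **VP_i** — weighted mean of the *product-line-specific* variables
  (e.g. HACCP certification for food, pharmacovigilance for drugs);
- **SOA_i** — the product-risk component: each product risk carries
  Severity, Occurrence and Affectation scores (each 1–5) and is standardized
  as (S·O·A)^(1/3), mapping the 1–125 product back to the 1–5 scale; risks
  are aggregated by maximum (default) or mean.

The aggregated risk index is the convex combination

    IRA_i = β₁·VT_i + β₂·VP_i + β₃·SOA_i,   β₁ + β₂ + β₃ = 1,

banded as **bajo** [1,2), **moderado** [2,3), **alto** [3,4),
**muy alto** [4,5]. Variable weights are estimated from historical panels by
single-component categorical PCA with optimal scaling (monotone
re-quantification of the 1–5 categories via alternating least squares);
the betas come from a one-factor model on the (VT, VP, SOA) columns — in
both cases squared loadings normalized to sum 1. At portfolio level the
package ranks establishments (descending IRA, ties by SOA then id),
computes the corporate index **IRAC** (90th percentile of IRA), the
band-by-product-line summary table, and the effectiveness indicator
(sanitary measures per 100 inspection visits).

## Worked example

The package ships the published dairy-establishment example as a fixture:

```python
import ivcsoa as iv

record, config = iv.dairy_example()
p = iv.score_establishment(record, config)
print(iv.round_half_up(p.vt), iv.round_half_up(p.vp),
      iv.round_half_up(p.soa), iv.round_half_up(p.ira), p.band.value)
```

prints

```
3.04 4.27 4.22 3.7 alto
```

i.e. the seven transversal scores (4, 3, 3, 2, 3, 2, 5) with weights
(11.24, 18.52, 5.08, 22.50, 13.43, 14.32, 14.90)% give VT = 3.04; the food
variables (5, 4, 3) with weights (37, 53, 10)% give VP = 4.27; the single
microbiological product risk S=5, O=3, A=5 gives (75)^(1/3) = 4.22; and
0.45·VT + 0.25·VP + 0.30·SOA = 3.70, a *high-risk* establishment that
should be prioritized for inspection.

The same run is available from the shell:

```bash
ivcsoa score --registry registry.csv --risks risks.csv \
             --config config.yaml --out scored.csv
ivcsoa report --profiles scored.csv --out-dir report/
ivcsoa weights --panel panel.csv --out weights.yaml
ivcsoa simulate --out-dir sim/ --n 500 --seed 7
```

## Layout

- `src/ivcsoa/domain.py` — types, reference tables, config validation, registry I/O
- `src/ivcsoa/scoring.py` — VT/VP/SOA components, IRA, banding
- `src/ivcsoa/weights.py` — optimal-scaling PCA weights, one-factor betas
- `src/ivcsoa/portfolio.py` — ranking, IRAC, summary table, effectiveness
- `src/ivcsoa/synthetic.py` — latent-factor portfolio generator, worked-example fixture
- `src/ivcsoa/cli.py` — `ivcsoa` command-line tool
- `docs/methods.md` — modeling and numerical choices in detail
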