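# glioqsar

QSAR modeling toolkit for dihydropteridone PLK1 inhibitors — a compound
class under investigation as anti-glioblastoma chemotherapeutics.  The
package re-implements, as a tested reusable library, the complete 2D/3D
workflow used to model this series:

* **dataset handling** — the published 34-compound activity table
  (IC50 in µM) ships as a fixture; activities are modeled on the potency
  scale `pAct = 9 − log10(IC50/µM)` and split into seeded train/test
  (1:3) or train/validation (1:4) partitions;
* **heuristic linear modeling (HM)** — collinearity prefiltering
  (pairwise |r| < 0.80) and greedy forward descriptor selection scored by
  R², leave-one-out R²cv, s², F and t statistics, plus a verbatim
  evaluator for the published six-descriptor equation

  ```
  pAct = −24.280 + 0.29798·NFA + 0.44403·MRCH + 5.6298·MECN
         − 0.57965·TEIZP + 3.6953·ZXS − 3.8370·MCIHN
  ```

* **gene expression programming (GEP)** — a full symbolic-regression
  engine over fixed-length Karva genomes (function set `+ − * / inv sin`),
  with elite roulette selection, mutation, IS/RIS/gene transposition and
  one/two-point/gene recombination, plus a parser/evaluator for the
  published nonlinear equation;
* **CoMSIA-style 3D-QSAR** — Kabsch scaffold alignment, five Gaussian
  similarity fields (steric, electrostatic, hydrophobic, donor, acceptor)
  on a 2 Å grid extended 4 Å beyond the molecules, PLS with a LOO Q² scan
  for the optimal number of components, field contribution fractions, and
  percentile contour maps exported as OpenDX grids;
* **validation statistics** — external R²ext, the rm² family
  (`rm² = r²(1 − √(r² − r0²))`), and 20× Y-randomization summarized by
  `R²p = r²·√(r² − mean r²_scrambled)`;
* **candidate design** — seeded enumeration of template analogs from an
  explicit modification library and ranking by any fitted model.

The commercial descriptor and field engines used by the original study are
not redistributable, so a first-class synthetic-data module generates
inputs with the same statistical structure (34 compounds × 500 collinear
descriptors with a planted six-descriptor truth; pseudo-aligned molecules
whose field columns drive activity through a planted coefficient map),
giving every stage a known ground truth to recover.

## Worked example

Run the full synthetic pipeline (simulate → hm → gep → comsia → validate →
design) from the command line:

```bash
glioqsar report --seed 1 --out run1
```

```
simulate: ok
hm: ok
gep: ok
comsia: ok
validate: ok
design: ok
```

`run1/hm_trace.csv` holds the forward-selection trace — on the seed-1
preset the first chosen descriptor is the strongest planted one (MECN) and
R²/R²cv climb as descriptors are added:

```
k,descriptors,r2,r2_cv,s2
1,MECN,0.4485,0.3529,0.0221
2,MECN+D0379,0.5761,0.4865,0.0175
...
8,MECN+...+D0312,0.9454,0.8987,0.0028
```

`run1/comsia_stats.yaml` reports the field-PLS diagnostics on the planted
3D preset — a LOO Q² of 0.894 at 5 components with R² 0.985, i.e. the
planted field–activity relationship is found and cross-validates:

```yaml
q2: 0.8936
onc: 5
r2: 0.9851
see: 1.0358
fractions: {S: 0.878, E: 0.006, H: 0.077, D: 0.018, A: 0.021}
```

`run1/validation.yaml` carries R²ext, rm² and the Y-randomization R²p for
the linear model (all above the conventional 0.5 acceptance threshold on
this preset), and `run1/design_ranking.csv` ranks 200 designed analogs of
the template molecule by predicted activity, best first.

Python API sketch:

```python
import glioqsar as gq

compounds = gq.load_table1()                      # 34 records, pAct 8.97-9.74
train, test = gq.split_dataset(compounds, gq.SplitSpec(seed=0))  # 26 / 8

model = gq.reference_hm_model()                   # published 6-term equation
model.predict({n: 0.0 for n in model.terms})      # -24.28

tree = gq.published_gep_model()                   # published GEP equation
gq.evaluate_tree(tree, dict(TEIZP=2, NFA=1, MECN=5,
                            MRCH=1, MCIHN=0.5, ZXS=1))  # 2.9111
```

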