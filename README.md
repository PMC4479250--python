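# qdbkit

A toolkit for **QSAR DataBank (QDB) model archives** — the packaging format in
which a published (Q)SAR model travels together with everything needed to
audit and reuse it: the compounds (with CAS numbers and InChI identifiers),
the experimental endpoint values, the descriptor values, the model's
mathematical representation, and the predictions it made on its training,
validation and testing sets.

qdbkit is aimed at model developers who deposit archives, repository
maintainers who must quality-control them, and model end users who want to
rerun or extend deposited models. It provides:

- **Archive I/O** — the ZIP container with XML registries and TSV value
  cargos, read and written byte-deterministically, plus a normalized
  "internal" variant with precomputed applicability-domain parameters.
- **Three-level validation**
  - *basic* (sanity testing): required attributes, declared cargos present
    and parseable, CAS check digits, InChI layer syntax, strong and weak
    reference resolution;
  - *intermediate* (reusability testing): every compound has an InChI, every
    property has both endpoint attributes and a UCUM unit cargo, every
    descriptor names the software that produced it;
  - *advanced* (reproducibility testing): every model is re-evaluated from
    its stored descriptor data and compared with its stored predictions.
- **Model evaluation** — a small arithmetic equation dialect (linear or any
  expression over `+ - * / ^`, `ln`, `log10`, `exp`, `sqrt`, `abs`;
  classification as a thresholded score), regression statistics
  (n, R², RMSE, MAE), confusion matrices and residual tables.
- **Applicability-domain analytics** — leverage
  h(x) = [1, x] (XᵀX)⁻¹ [1, x]ᵀ with the Williams-plot warning threshold
  h\* = 3(d+1)/n, Mahalanobis distance
  √((x−c)ᵀ S⁻¹ (x−c)) from the training centroid, standardized residuals,
  Williams/Gramatica (Insubria) plot data, and Euclidean nearest-neighbour
  similarity.
- **A prediction engine** — from a structure (via pluggable descriptor
  calculators), from manual descriptor values, or from the raw data stored in
  the archive; single or batch mode; every prediction annotated with AD
  distances and its most similar dataset compounds.
- **A synthetic-archive generator** — seeded, byte-reproducible fixtures with
  a known linear ground truth and injectable defects, so every part of the
  toolkit is testable without downloading deposited data.

## Worked example

```python
import qdbkit as q

archive = q.generate(q.FixtureSpec(seed=7))      # 32 compounds, 2 descriptors
print(q.validate(archive, "advanced").to_text())
# validation level: advanced
# outcome: clean

result = q.predict_manual(archive, "model1", {"logp": 2.0, "mw": 150.0}, k=3)
print(round(result.value, 4))                    # 0.4
print(round(result.leverage, 4), result.inside_domain)
# 0.0624 True
for cid, dist, exp, pred in result.neighbours:
    print(cid, round(dist, 3), round(exp, 3), round(pred, 3))
# c27 0.268 0.64 0.407
# c30 2.538 0.676 0.737
# c26 4.531 -0.261 0.082

stats = q.regression_stats(
    archive.properties["activity"].values_table(),
    archive.predictions["training"].values_table())
print(stats.n, round(stats.r2, 3), round(stats.rmse, 3))
# 22 0.914 0.222
```

The prediction 0.4 is the model equation evaluated at the entered descriptor
values; the leverage 0.0624 is well below the warning threshold
3·(2+1)/22 ≈ 0.409, so the query sits inside the model's applicability
domain, and the three nearest training compounds (by raw Euclidean distance
in descriptor space) give experimental context for judging the prediction.

The same operations are available from the shell:

```sh
qdb make-fixture --seed 7 --out demo.qdb     # prints the archive's SHA-256
qdb validate demo.qdb --level advanced       # exit 0 clean/warnings, 1 failed
qdb predict demo.qdb --model model1 --compound c1
qdb report demo.qdb --out report/            # data table, stats, Williams data
```

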