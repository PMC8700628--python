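# ibdclass

Two-stage PLS-DA / sparse PLS-DA classification of Crohn's disease (CD)
versus ulcerative colitis (UC) from mucosal RNA-seq counts.

## The problem

CD and UC, the two main inflammatory bowel disease subtypes, overlap
clinically but need different long-term management, which motivates a
molecular classifier built from endoscopic biopsy transcriptomes. Biopsies
come labelled by disease (CD/UC) and status (inflamed/normal), and the
normal-tissue samples carry a confound: they are taken mostly from the
terminal ileum in CD and the rectum in UC, so genes separating the normal
classes largely track gut segment rather than disease. `ibdclass`
implements the two-stage workaround as a tested, reusable pipeline:

1. **Preprocess** — low-count filtering, TMM effective-library-size
   normalization, log2-CPM with a depth-scaled prior count; PCA overview.
2. **Stage 1** — fit a PLS-DA to normal samples (CD-normal vs UC-normal);
   score every gene by |p_g · d|, the projection of its loading vector
   p_g on the unit direction d connecting the class centroids in score
   space; evaluate the classifier after pruning the top 1/4, 1/2, 3/4 of
   genes (the "trench" table).
3. **Prune** — drop the top half of genes by that score: the strong
   normal-tissue (segment) discriminators.
4. **Stage 2** — on inflamed samples and the surviving genes, pick the
   PLS-DA component count H by repeated 5-fold CV, tune the number of
   genes per component (keepX) of a sparse PLS-DA over a grid by repeated
   stratified CV on the balanced error rate, and report the final model's
   cross-validated overall (OER) and balanced (BER) error rates.

PLS-DA maximizes cov(Xw, Yq) between gene expression and a centered class
indicator; the sparse variant soft-thresholds each weight vector so
exactly keepX genes per component carry nonzero weight. A synthetic-data
module generates four-class negative-binomial count matrices (default
class sizes 29/65/20/13, variance μ + φμ²) with planted inflammation,
disease and segment gene sets, so the whole pipeline runs with no
external download. See `docs/methods.md` for the model details and every
pinned convention.

## Worked example

```python
import ibdclass as ib

counts, meta, truth = ib.simulate_counts(ib.SimConfig(seed=1))
cfg = ib.AnalysisConfig(keepx_grid=(5, 10, 20, 50, 100), seed=1)
report = ib.run_two_stage(counts, meta, cfg)

print(report.trench_table[["fraction", "stage1_oer", "stage2_oer"]])
print("chosen ncomp:", report.chosen_ncomp, "keepX:", report.tuning.chosen)
print("final CV OER: %.3f  BER: %.3f" % (report.final_cv.oer, report.final_cv.ber))
```

prints

```
   fraction  stage1_oer  stage2_oer
0      0.25    0.166667    0.106122
1      0.50    0.269231    0.104082
2      0.75    0.682051    0.144898
chosen ncomp: 3 keepX: (10, 5, 5)
final CV OER: 0.000  BER: 0.000
```

Reading this: pruning more genes degrades the *normal*-tissue classifier
monotonically (stage-1 OER rising 0.17 → 0.27 → 0.68 as the planted
segment signal is cut away) while the *inflamed*-tissue classifier barely
moves — the confound, not the disease signal, is being removed. On the
pruned gene set the tuned sparse model keeps 10 + 5 + 5 genes over three
components and classifies the 29 CD-inflamed vs 20 UC-inflamed samples
with zero cross-validated error, the planted disease effect (log2FC 1.5,
φ = 0.1) being strong at this depth.

The same run from a shell:

```sh
ibdclass simulate --outdir data --seed 1
ibdclass run --counts data/counts.tsv --meta data/metadata.tsv \
    --keepx-grid 5,10,20,50,100 --seed 1 --outdir results
ibdclass report --report results/report.json
```

`run` writes `report.json` plus TSV exports (per-component gene
signatures, trench table, tuning curves, PCA scores, pruning scores);
re-running with the same seed reproduces them byte-for-byte.

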