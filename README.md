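# oligoscore

Prototype-based scoring of oligodendrocyte-lineage states in single-nucleus
RNA-seq of multiple-sclerosis (MS) brain tissue, with the surrounding
analysis stack: QC and clustering, inflammatory gene-module scoring,
kNN-neighborhood differential abundance, permutation-based ligand–receptor
communication tests, and Wilcoxon differential expression with
over-representation analysis.

## The problem

In adult human white matter, oligodendrocyte progenitors and
oligodendrocytes at different maturation stages (pre-OPC, dividing-OPC,
late-OPC, COP, NFOL, MFOL, MOL) are hard to separate by unsupervised
clustering: the genes that distinguish early lineage states fade with age.
A supervised alternative is to train a classifier on a *developmental
reference atlas*, where those states are abundant and marker-confirmed,
and to score every oligodendrocyte-lineage cell in adult/MS tissue by its
similarity to each developmental prototype. Comparing the resulting
subtype compositions across lesion regions (control white matter, NAWM,
chronic-active and chronic-inactive lesion cores and edges) quantifies
where remyelination-competent states are missing.

## The model

Let `x_i` be the log-normalized, standardized expression of cell `i` over
the reference's top highly variable genes and `K` the prototype classes.
The scorer is a multinomial logistic (softmax) model with an L2 penalty:

    s_ik = exp(w_k' x_i + b_k) / sum_j exp(w_j' x_i + b_j)
    min_W  -(1/n) sum_i log s_{i,y_i}  +  (lambda/2) ||W||_2^2

`s_ik in [0,1]` is the **similarity score** of cell `i` to prototype `k`;
rows sum to 1. A cell is assigned the argmax class only when its top score
reaches `tau = 0.70` (since `tau > 0.5`, at most one class can qualify);
otherwise it is *unassigned* — the model's way of flagging cells that match
no prototype. The penalty `lambda` is swept over a log grid with 5-fold
stratified cross-validation; the chosen `lambda*` is the strongest penalty
whose CV accuracy stays within one confidence half-width of the best *and*
which still assigns at least 95% of held-out reference cells at `tau` —
maximal shrinkage that does not push genuine prototype members below the
threshold. A wheel plot places each cell at the score-weighted average of
the `K` class vertices on the unit circle.

Everything runs on synthetic data from the built-in generator
(`oligoscore.simulate`), which emulates the study design: a 7-subtype
developmental reference with the canonical marker programs (EGFR/NES/
ZFP36L1/GFAP for pre-OPC, …, with GPR17 deliberately shared between COP
and NFOL), and a six-region MS query in which pre-OPC and NFOL are present
in Control/NAWM, absent from lesion cores, and rare at edges; microglia
split into inflamed and homeostatic states; and SIRPA–CD47, CD74–MIF and
CSF1R–CSF1 switch on and off by region.

## Worked example

```python
from oligoscore import *
from oligoscore.simulate import SimConfig

cfg = SimConfig(seed=0)

# developmental reference atlas -> prototype model
ref_counts, ref_meta, _ = generate_reference_atlas(cfg)
model = PrototypeScorer(normalize_log(ref_counts), ref_meta["subtype"]).fit(seed=0)
print(model.summary())

# six-region MS query -> QC -> score the OL-lineage cells
q_counts, q_meta, truth = generate_ms_query(cfg)
q_filtered, report = qc_filter(q_counts)          # 200-6000 genes, <5% mito
q_norm = normalize_log(q_filtered)                # ln(1 + x/libsize * 1e4)
# ... subset to OPC/OL cells, then:
scores = model.score(q_norm_ol)                   # softmax similarity scores
table = assign_and_tabulate(scores, q_meta_ol)    # region x subtype fractions
```

Output (abridged):

```
Prototype scorer (multinomial L2 logistic)
============================================
classes:        7 (COP, Dividing-OPC, Late-OPC, MFOL, MOL, NFOL, Pre-OPC)
genes:          2000
lambda*:        1
CV accuracy:    0.997 +/- 0.003

QC: kept 3234/3600 cells

label    Pre-OPC   NFOL    MOL  unassigned
region
CA         0.000  0.000  0.494       0.006
CA_edge    0.072  0.063  0.455       0.025
CI         0.000  0.000  0.546       0.018
CI_edge    0.070  0.065  0.443       0.018
Control    0.123  0.125  0.360       0.018
NAWM       0.157  0.157  0.294       0.022
```

Reading the table: pre-OPC and NFOL are detected at substantial fractions
in control white matter and NAWM, drop to exactly zero in both lesion
cores (CA, CI) — where the generator planted their absence — and appear at
reduced fractions at lesion edges. MOL enrichment in cores is a
composition effect (the denominator shrinks when early states vanish).

The same pipeline is scriptable end to end:

```bash
oligoscore run-all --seed 1 --out-dir run1      # simulate ... deg, one seed
oligoscore simulate --seed 3 --out-dir sim      # or stage by stage
oligoscore qc --counts-dir sim/query --out-dir qcd
```

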