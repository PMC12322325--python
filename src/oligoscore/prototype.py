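"""Prototype-based supervised scoring of oligodendrocyte-lineage states.

A multinomial, L2-regularized logistic ("softmax") model is trained on a
labeled reference atlas whose classes are marker-confirmed lineage states
(the prototypes).  The model's class probabilities are the similarity
scores: they sum to one per cell, and a query cell is assigned to a
subtype only when its top score reaches a conservative threshold
(tau = 0.70 by default); otherwise it stays "unassigned".  Because
tau > 0.5, at most one class can reach it, so assignment is unique.

Training sweeps the penalty strength over a log grid, recording per-lambda
cross-validated accuracy, held-out log-likelihood, confidence, the
assignment rate at tau, and the total absolute weight.  The chosen penalty
is the strongest one that keeps CV accuracy within one confidence
half-width of the best (a one-standard-error-style rule) while still
assigning at least 95% of held-out reference cells at tau -- reference
cells are all genuine prototype members, so losing more of them to the
"unassigned" bucket signals over-shrinkage, while weaker penalties leave
overfit weight on uninformative genes that inflates the scores of cells
matching no prototype.  Features are the top
highly variable genes of the reference, standardized with training-set
statistics that are frozen for query scoring; query genes missing from
the model contribute the training mean (standardized 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .params import PipelineParams
from .preprocess import NormMatrix, select_hvgs

logger = logging.getLogger("oligoscore")

MODEL_FORMAT_VERSION = 1


class ScoringError(ValueError):
    """Invalid input to training or scoring."""


# --------------------------------------------------------------------------
# Result containers


@dataclass
class SimilarityScoreTable:
    """Per-cell class probabilities plus thresholded subtype labels."""

    scores: pd.DataFrame       # cells x classes, rows sum to 1
    assigned: pd.Series        # class name or "unassigned", indexed by cell_id
    tau: float

    @property
    def classes(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class WheelCoordinates:
    """Radial projection: class k sits at angle 2*pi*k/K on the unit circle
    and each cell is the score-weighted average of the class vertices."""

    points: pd.DataFrame       # cells x (x, y)
    vertices: pd.DataFrame     # classes x (x, y)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _standardize_stats(X: np.ndarray, sd_floor: float = 1e-8):
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0, ddof=0), sd_floor)
    return mu, sd


def _fit_softmax(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-6):
    """One multinomial L2 fit; returns (W [K x G], b [K]) in class-sorted order."""
    clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", tol=tol, max_iter=3000)
    clf.fit(X, y)
    classes = list(clf.classes_)
    if len(classes) == 2:
        # sklearn parameterizes binary fits with a single weight vector;
        # expand to the equivalent two-row softmax form.
        W = np.vstack([np.zeros_like(clf.coef_[0]), clf.coef_[0]])
        b = np.array([0.0, clf.intercept_[0]])
    else:
        W, b = clf.coef_, clf.intercept_
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
        raise ScoringError(f"non-finite optimum at lambda={lam}")
    return classes, W, b


# --------------------------------------------------------------------------
# Model


class PrototypeScorer:
    """Multinomial prototype model of lineage states (statsmodels-style).

    Parameters
    ----------
    ref_nm
        Log-normalized reference expression (genes x cells).
    labels
        Per-cell subtype labels aligned with ``ref_nm.cell_ids``.
    params
        Pipeline parameters; ``n_hvg_ml`` caps the candidate gene count
        and ``seed`` controls CV fold assignment (the convex solver
        itself is deterministic).
    """

    MIN_CLASS_SIZE = 20
    # lambda* keeps at least this fraction of held-out reference cells above
    # the assignment threshold tau (see fit()).
    MIN_COVERAGE = 0.95

    def __init__(
        self,
        ref_nm: NormMatrix,
        labels,
        params: PipelineParams | None = None,
        genes: list[str] | None = None,
    ):
        self.params = params or PipelineParams()
        labels = np.asarray(labels, dtype=object)
        if len(labels) != ref_nm.n_cells:
            raise ScoringError("labels must align with reference cells")
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ScoringError("need at least 2 classes")
        small = classes[counts < self.MIN_CLASS_SIZE]
        if small.size:
            raise ScoringError(
                f"class(es) below {self.MIN_CLASS_SIZE} cells: {list(small)}"
            )
        self.ref_nm = ref_nm
        self.labels = labels
        if genes is None:
            n_feat = min(self.params.n_hvg_ml, ref_nm.n_genes)
            genes = select_hvgs(ref_nm, n_feat).genes
        self.genes = list(genes)
        gi = ref_nm.gene_index()
        rows = [gi[g] for g in self.genes]
        self._X_raw = ref_nm.values[rows].toarray().T.astype(float)  # cells x genes

    def fit(
        self,
        lambda_grid: np.ndarray | None = None,
        n_folds: int = 5,
        seed: int | None = None,
    ) -> "PrototypeResults":
        """Sweep the L2 penalty, pick lambda* by the one-SE-style rule,
        and refit on all reference cells."""
        if lambda_grid is None:
            lambda_grid = np.logspace(-3, 3, 13)
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
        seed = self.params.seed if seed is None else seed

        mu, sd = _standardize_stats(self._X_raw)
        X = (self._X_raw - mu) / sd
        y = self.labels

        rows = []
        fits = {}
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        tau = self.params.similarity_tau
        for lam in lambda_grid:
            accs, lls, confs, cover = [], [], [], []
            for tr, va in splits:
                cls, W, b = _fit_softmax(X[tr], y[tr], lam)
                col = {c: i for i, c in enumerate(cls)}
                probs_va = _softmax(X[va] @ W.T + b)
                pred = np.asarray(cls, dtype=object)[np.argmax(probs_va, axis=1)]
                accs.append(float(np.mean(pred == y[va])))
                confs.append(float(np.mean(probs_va.max(axis=1))))
                cover.append(float(np.mean(probs_va.max(axis=1) >= tau)))
                true_p = probs_va[np.arange(len(va)), [col[c] for c in y[va]]]
                lls.append(float(np.mean(np.log(np.maximum(true_p, 1e-300)))))
            cls, W, b = _fit_softmax(X, y, lam)
            probs = _softmax(X @ W.T + b)
            col = {c: i for i, c in enumerate(cls)}
            ll = float(
                np.mean(np.log(np.maximum(probs[np.arange(len(y)), [col[c] for c in y]], 1e-300)))
            )
            fits[lam] = (cls, W, b)
            rows.append(
                {
                    "lam": lam,
                    "cv_accuracy": float(np.mean(accs)),
                    "ci_halfwidth": float(1.96 * np.std(accs, ddof=0) / np.sqrt(len(accs))),
                    "cv_loglik": float(np.mean(lls)),
                    "cv_loglik_ci": float(1.96 * np.std(lls, ddof=0) / np.sqrt(len(lls))),
                    "cv_confidence": float(np.mean(confs)),
                    "cv_assign_rate": float(np.mean(cover)),
                    "assign_ci_halfwidth": float(
                        1.96 * np.std(cover, ddof=0) / np.sqrt(len(cover))
                    ),
                    "sum_abs_weight": float(np.abs(W).sum()),
                    "train_loglik": ll,
                }
            )
        sweep = pd.DataFrame(rows)
        # lambda* selection.  Eligibility: CV accuracy within one confidence
        # half-width of the best (one-SE-style; the half-width is floored at
        # one misclassified cell, 1/n, since a perfect-accuracy fold set has
        # zero spread and would otherwise collapse the band).  Among eligible
        # penalties, take the STRONGEST whose held-out assignment rate -- the
        # fraction of cells whose top probability clears tau -- stays at or
        # above MIN_COVERAGE.  Reference cells are all genuine prototype
        # members, so a model that leaves more than ~5% of them unassigned is
        # over-shrunk; below that, maximal shrinkage is preferred because
        # weakly penalized fits put overfit weight on uninformative genes,
        # inflating the scores of cells that match no prototype.
        best = sweep.loc[sweep["cv_accuracy"].idxmax()]
        acc_floor = best["cv_accuracy"] - max(best["ci_halfwidth"], 1.0 / len(y))
        eligible = sweep[sweep["cv_accuracy"] >= acc_floor]
        covered = eligible[eligible["cv_assign_rate"] >= self.MIN_COVERAGE]
        if len(covered):
            lam_star = float(covered["lam"].max())
        else:
            lam_star = float(eligible.loc[eligible["cv_assign_rate"].idxmax(), "lam"])
        cls, W, b = fits[lam_star]
        at = sweep.loc[sweep["lam"] == lam_star].iloc[0]
        logger.info(
            "prototype fit: lambda*=%.4g (CV assignment rate %.3f at tau=%.2f), "
            "CV accuracy %.3f, %d genes, %d classes",
            lam_star, at["cv_assign_rate"], tau, at["cv_accuracy"],
            len(self.genes), len(cls),
        )
        return PrototypeResults(
            model=self,
            classes=list(cls),
            genes=list(self.genes),
            W=W,
            b=b,
            feature_mean=mu,
            feature_sd=sd,
            lambda_=lam_star,
            sweep=sweep,
        )


# --------------------------------------------------------------------------
# Results


@dataclass
class PrototypeResults:
    """Fitted prototype model: weights, penalty trace, and scoring methods."""

    classes: list[str]
    genes: list[str]
    W: np.ndarray              # classes x genes, standardized feature space
    b: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    lambda_: float
    sweep: pd.DataFrame
    model: PrototypeScorer | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if self.model is not None:
            self.params = self.model.params

    # -- scoring ------------------------------------------------------------

    def score(self, query_nm: NormMatrix, tau: float | None = None) -> SimilarityScoreTable:
        """Score query cells; softmax class probabilities plus assignment.

        Query genes missing from the model are imputed at the training
        mean (standardized value 0); more than 50% missing is an error.
        """
        tau = self.params.similarity_tau if tau is None else tau
        gi = query_nm.gene_index()
        present = [(j, gi[g]) for j, g in enumerate(self.genes) if g in gi]
        n_missing = len(self.genes) - len(present)
        if n_missing > 0.5 * len(self.genes):
            raise ScoringError(
                f"{n_missing}/{len(self.genes)} model genes missing from query"
            )
        if n_missing:
            logger.info("score: %d model gene(s) missing from query, imputed as 0",
                        n_missing)
        X = np.zeros((query_nm.n_cells, len(self.genes)))
        cols_model = [j for j, _ in present]
        rows_query = [r for _, r in present]
        Xq = query_nm.values[rows_query].toarray().T.astype(float)
        X[:, cols_model] = (Xq - self.feature_mean[cols_model]) / self.feature_sd[cols_model]
        probs = _softmax(X @ self.W.T + self.b)
        scores = pd.DataFrame(probs, index=list(query_nm.cell_ids), columns=self.classes)
        top = probs.max(axis=1)
        arg = np.asarray(self.classes, dtype=object)[np.argmax(probs, axis=1)]
        assigned = pd.Series(
            np.where(top >= tau, arg, "unassigned"),
            index=list(query_nm.cell_ids),
            name="assigned",
        )
        return SimilarityScoreTable(scores=scores, assigned=assigned, tau=tau)

    # -- gene reduction -----------------------------------------------------

    def reduce_genes(self, top_n: int, seed: int | None = None) -> "PrototypeResults":
        """Keep the top_n genes by max-class |weight| and refit at lambda*."""
        if self.model is None:
            raise ScoringError("reduce_genes requires the training model")
        if top_n < len(self.classes):
            raise ScoringError(f"top_n must be >= number of classes ({len(self.classes)})")
        if top_n > len(self.genes):
            raise ScoringError(f"top_n={top_n} exceeds {len(self.genes)} model genes")
        strength = np.abs(self.W).max(axis=0)
        order = np.lexsort((np.asarray(self.genes, dtype=str), -strength))
        keep = sorted(order[:top_n])
        genes = [self.genes[i] for i in keep]
        sub = PrototypeScorer(self.model.ref_nm, self.model.labels,
                              params=self.params, genes=genes)
        res = sub.fit(lambda_grid=np.array([self.lambda_]), seed=seed)
        full_acc = float(
            self.sweep.loc[self.sweep["lam"] == self.lambda_, "cv_accuracy"].iloc[0]
        )
        red_acc = float(res.sweep["cv_accuracy"].iloc[0])
        if red_acc < full_acc - 0.05:
            logger.warning(
                "reduce_genes: CV accuracy dropped from %.3f to %.3f", full_acc, red_acc
            )
        return res

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        at = self.sweep.loc[self.sweep["lam"] == self.lambda_].iloc[0]
        lines = [
            "Prototype scorer (multinomial L2 logistic)",
            "=" * 44,
            f"classes:        {len(self.classes)} ({', '.join(self.classes)})",
            f"genes:          {len(self.genes)}",
            f"lambda*:        {self.lambda_:.4g}  (strongest penalty within one "
            f"SE of best CV accuracy with assignment rate >= "
            f"{PrototypeScorer.MIN_COVERAGE:g}; {len(self.sweep)} grid points)",
            f"CV accuracy:    {at['cv_accuracy']:.3f} +/- {at['ci_halfwidth']:.3f}",
            f"sum |W|:        {at['sum_abs_weight']:.2f}",
            f"train loglik:   {at['train_loglik']:.4f}",
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        blob = {
            "format_version": MODEL_FORMAT_VERSION,
            "classes": self.classes,
            "genes": self.genes,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "lambda": self.lambda_,
            "sweep": self.sweep.to_dict(orient="list"),
            "similarity_tau": self.params.similarity_tau,
        }
        Path(path).write_text(json.dumps(blob))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "PrototypeResults":
        blob = json.loads(Path(path).read_text())
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ScoringError(f"unsupported model format: {blob.get('format_version')}")
        params = PipelineParams(similarity_tau=blob["similarity_tau"])
        return cls(
            classes=blob["classes"],
            genes=blob["genes"],
            W=np.asarray(blob["W"]),
            b=np.asarray(blob["b"]),
            feature_mean=np.asarray(blob["feature_mean"]),
            feature_sd=np.asarray(blob["feature_sd"]),
            lambda_=blob["lambda"],
            sweep=pd.DataFrame(blob["sweep"]),
            model=None,
            params=params,
        )


# --------------------------------------------------------------------------
# Convenience functions (spec-level operations)


def train_prototype_model(
    ref_nm: NormMatrix,
    labels,
    params: PipelineParams | None = None,
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> PrototypeResults:
    return PrototypeScorer(ref_nm, labels, params).fit(lambda_grid=lambda_grid, seed=seed)


def score_cells(results: PrototypeResults, query_nm: NormMatrix,
                tau: float | None = None) -> SimilarityScoreTable:
    return results.score(query_nm, tau=tau)


def assign_and_tabulate(scores: SimilarityScoreTable, cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-region counts and fractions of each assigned subtype.

    ``cell_table`` must cover exactly the scored cells; fractions sum to 1
    within each region (including the "unassigned" bucket).
    """
    ids = list(scores.assigned.index)
    meta = cell_table.set_index("cell_id")
    missing = [c for c in ids if c not in meta.index]
    if missing or len(ids) != len(meta):
        raise ScoringError("cell ids of scores and cell table do not match")
    df = pd.DataFrame(
        {"region": meta.loc[ids, "region"].to_numpy(), "label": scores.assigned.to_numpy()}
    )
    out = (
        df.groupby(["region", "label"], sort=True).size().rename("n").reset_index()
    )
    totals = out.groupby("region")["n"].transform("sum")
    out["fraction"] = out["n"] / totals
    return out


def wheel_coordinates(scores: SimilarityScoreTable, class_order: list[str] | None = None) -> WheelCoordinates:
    """Project cells onto the prototype wheel.

    Vertex k of the K-gon sits at angle 2*pi*k/K; a cell's point is the
    score-weighted average of the vertices, so a pure one-hot score lands
    exactly on its vertex and a uniform score at the origin.
    """
    class_order = class_order or scores.classes
    K = len(class_order)
    if K < 3:
        raise ScoringError("wheel plot needs at least 3 classes")
    S = scores.scores[class_order].to_numpy()
    sums = S.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ScoringError("score rows must sum to 1")
    ang = 2.0 * np.pi * np.arange(K) / K
    V = np.column_stack([np.cos(ang), np.sin(ang)])
    P = S @ V
    return WheelCoordinates(
        points=pd.DataFrame(P, index=scores.scores.index, columns=["x", "y"]),
        vertices=pd.DataFrame(V, index=class_order, columns=["x", "y"]),
    )
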