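"""Utility-evaluation protocol: experiment planning, k-fold cross-validation
with a lightweight classifier, F1 aggregation, and pairwise one-sided
Mann-Whitney U comparisons.

The protocol mirrors how the impact of pseudonymization on downstream
predictive performance is assessed: every combination of model x data version
(original / pseudonymized variants) x task is fine-tuned and tested with
k-fold cross-validation (default k=10), and for each task every ordered pair
of configurations is compared with a one-sided Mann-Whitney U test over the
k fold-wise F1 scores — does the weaker candidate score systematically below
the stronger one?

The classifier is deliberately lightweight — a term-frequency linear model
trained for at most 10 epochs with early stopping for document tasks, a
per-token lexical tagger for token tasks.  The object of study is the
protocol and its statistics, not absolute scores.

The Mann-Whitney U implementation is exact for small samples: the no-tie
null distribution comes from the classical counting recurrence, tied samples
are handled with mid-ranks and full permutation enumeration for n+m <= 20,
and larger samples use the normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import KFold
from sklearn.naive_bayes import MultinomialNB

from .schema import AnnotatedDocument, ValidationError, tokenize

__all__ = [
    "ExperimentPlan",
    "Configuration",
    "FoldScores",
    "ComparisonResult",
    "build_plan",
    "kfold_split",
    "train_eval_fold",
    "f1_score",
    "span_f1",
    "mann_whitney_u",
    "comparison_matrix",
    "report_tables",
    "holm_adjust",
]


# ------------------------------------------------------------------ planning

@dataclass(frozen=True)
class Configuration:
    """One experimental cell: a model trained on one data version for one task."""

    model: str
    data_version: str
    task: str

    @property
    def config_id(self) -> str:
        return f"{self.model}|{self.data_version}|{self.task}"


@dataclass
class ExperimentPlan:
    """Full factorial plan over models x data versions x tasks, k folds each."""

    models: list[str]
    data_versions: list[str]
    tasks: list[str]
    k: int = 10
    seed: int = 0

    @property
    def configurations(self) -> list[Configuration]:
        return [
            Configuration(m, v, t)
            for t in self.tasks
            for m in self.models
            for v in self.data_versions
        ]

    @property
    def n_configurations(self) -> int:
        return len(self.models) * len(self.data_versions) * len(self.tasks)

    @property
    def n_runs(self) -> int:
        return self.n_configurations * self.k

    def runs(self) -> list[tuple[Configuration, int]]:
        return [(c, fold) for c in self.configurations for fold in range(self.k)]


def build_plan(
    models: Sequence[str],
    data_versions: Sequence[str],
    tasks: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> ExperimentPlan:
    """Enumerate every configuration and fold with stable identifiers.

    Pseudonymization is a deterministic pre-processing step, so a
    configuration trained on a pseudonymized version is also *tested* on the
    pseudonymized folds; the executor enforces this by splitting folds on
    document indices shared across versions of the same task.
    """
    for name, axis in [("models", models), ("data_versions", data_versions), ("tasks", tasks)]:
        if not axis:
            raise ValidationError(f"experiment axis {name!r} is empty")
    if k < 2:
        raise ValidationError(f"fold count k must be >= 2, got {k}")
    return ExperimentPlan(list(models), list(data_versions), list(tasks), k=k, seed=seed)


def kfold_split(
    docs: Sequence[AnnotatedDocument], k: int, seed: int
) -> list[tuple[list[AnnotatedDocument], list[AnnotatedDocument]]]:
    """Shuffled k-fold partition: test folds are disjoint, cover the corpus,
    and differ in size by at most one; deterministic under ``seed``."""
    if len(docs) < k:
        raise ValidationError(f"need at least k={k} documents, got {len(docs)}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    out = []
    for train_idx, test_idx in splitter.split(np.arange(len(docs))):
        out.append(
            ([docs[i] for i in train_idx], [docs[i] for i in test_idx])
        )
    return out


# ------------------------------------------------------------------ classifiers

def _doc_tokens(doc: AnnotatedDocument) -> list[str]:
    return [doc.text[a:b].lower() for a, b in tokenize(doc.text)]


_MODELS = ("tf-linear", "tf-nb")


def _make_doc_classifier(model: str, fit_seed: int):
    if model == "tf-nb":
        return MultinomialNB()
    # max 10 epochs with tol-based early stopping, mirroring a bounded
    # fine-tuning budget; fit_seed controls the epoch shuffling, playing the
    # role of per-run training stochasticity
    return SGDClassifier(
        loss="log_loss", max_iter=10, tol=1e-3, random_state=fit_seed & 0x7FFFFFFF,
        alpha=1e-4,
    )


def train_eval_fold(
    train_docs: Sequence[AnnotatedDocument],
    test_docs: Sequence[AnnotatedDocument],
    task_type: str,
    model: str = "tf-linear",
    fit_seed: int = 0,
) -> float:
    """Fit the lightweight task model on one fold and return its test F1.

    Document tasks use a term-count linear classifier (weighted F1); token
    tasks use a per-token lexical tagger scored with span-level micro F1.  A
    single-class training fold is degenerate: the constant prediction is
    scored and a warning is emitted.
    """
    if not test_docs:
        raise ValidationError("empty test fold")
    if model not in _MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {_MODELS}")
    if task_type == "doc_classification":
        y_train = [d.label for d in train_docs]
        y_test = [d.label for d in test_docs]
        if any(l is None for l in itertools.chain(y_train, y_test)):
            raise ValidationError("doc_classification requires labeled documents")
        if len(set(y_train)) < 2:
            import warnings

            warnings.warn("single-class training fold; scoring constant prediction")
            y_pred = [y_train[0]] * len(y_test)
            return f1_score(y_pred, y_test, averaging="weighted")
        vec = CountVectorizer(analyzer=_doc_tokens, min_df=1)
        X_train = vec.fit_transform(train_docs)
        X_test = vec.transform(test_docs)
        clf = _make_doc_classifier(model, fit_seed)
        import warnings

        with warnings.catch_warnings():
            # stopping at the epoch cap is the intended budget, not a defect
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X_train, y_train)
        y_pred = clf.predict(X_test).tolist()
        return f1_score(y_pred, y_test, averaging="weighted")
    if task_type == "token_ner":
        return _train_eval_tagger(train_docs, test_docs)
    raise ValidationError(f"unknown task_type {task_type!r}")


def _train_eval_tagger(
    train_docs: Sequence[AnnotatedDocument], test_docs: Sequence[AnnotatedDocument]
) -> float:
    """Majority-vote lexical tagger: each token type maps to its most common
    training tag, unknown tokens to O; scored with span-level micro F1."""
    from collections import Counter, defaultdict

    votes: dict[str, Counter] = defaultdict(Counter)
    for doc in train_docs:
        if doc.token_tags is None:
            raise ValidationError(f"doc {doc.doc_id!r} lacks token_tags")
        for (a, b), tag in zip(tokenize(doc.text), doc.token_tags):
            votes[doc.text[a:b].lower()][tag] += 1
    lexicon = {tok: c.most_common(1)[0][0] for tok, c in votes.items()}
    gold_seqs, pred_seqs = [], []
    for doc in test_docs:
        if doc.token_tags is None:
            raise ValidationError(f"doc {doc.doc_id!r} lacks token_tags")
        toks = [doc.text[a:b].lower() for a, b in tokenize(doc.text)]
        pred_seqs.append([lexicon.get(t, "O") for t in toks])
        gold_seqs.append(list(doc.token_tags))
    return span_f1(pred_seqs, gold_seqs)


def f1_score(
    predicted: Sequence[str], gold: Sequence[str], averaging: str = "weighted"
) -> float:
    """Multi-class F1 over label sequences (micro / macro / weighted)."""
    if len(predicted) != len(gold):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predicted vs {len(gold)} gold"
        )
    if averaging not in ("micro", "macro", "weighted"):
        raise ValidationError(f"unknown averaging {averaging!r}")
    labels = sorted(set(gold) | set(predicted))
    return float(
        _sk_f1(gold, predicted, labels=labels, average=averaging, zero_division=0)
    )


def _bio_spans(tags: Sequence[str]) -> set[tuple[int, int, str]]:
    spans = set()
    start, cls = None, None
    for i, tag in enumerate(list(tags) + ["O"]):
        if tag.startswith("B-") or tag == "O" or (
            tag.startswith("I-") and tag[2:] != cls
        ):
            if cls is not None:
                spans.add((start, i, cls))
                start, cls = None, None
        if tag.startswith("B-"):
            start, cls = i, tag[2:]
        elif tag.startswith("I-") and cls is None:
            start, cls = i, tag[2:]  # tolerate dangling I- as a new span
    return spans


def span_f1(
    predicted: Sequence[Sequence[str]], gold: Sequence[Sequence[str]]
) -> float:
    """Span-level micro F1 over BIO tag sequences (exact span + class match)."""
    if len(predicted) != len(gold):
        raise ValidationError("length mismatch between predicted and gold sequences")
    tp = fp = fn = 0
    for p_seq, g_seq in zip(predicted, gold):
        if len(p_seq) != len(g_seq):
            raise ValidationError("tag sequence length mismatch within a document")
        p_spans, g_spans = _bio_spans(p_seq), _bio_spans(g_seq)
        tp += len(p_spans & g_spans)
        fp += len(p_spans - g_spans)
        fn += len(g_spans - p_spans)
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


# ------------------------------------------------------------------ Mann-Whitney

@lru_cache(maxsize=128)
def _u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution counts of U for untied samples of sizes n, m.

    counts[u] = number of orderings with U == u; sums to C(n+m, n).
    Classical recurrence f(u; n, m) = f(u - m; n - 1, m) + f(u; n, m - 1).
    """
    dp: list[list[np.ndarray | None]] = [
        [None] * (m + 1) for _ in range(n + 1)
    ]
    for j in range(m + 1):
        dp[0][j] = np.array([1.0])
    for i in range(1, n + 1):
        dp[i][0] = np.array([1.0])
        for j in range(1, m + 1):
            a = np.zeros(i * j + 1)
            prev_i = dp[i - 1][j]
            a[j : j + len(prev_i)] += prev_i
            prev_j = dp[i][j - 1]
            a[: len(prev_j)] += prev_j
            dp[i][j] = a
    return dp[n][m]


def _midrank_u(xs: np.ndarray, ys: np.ndarray) -> float:
    """U statistic for xs via mid-ranks of the pooled sample."""
    pooled = np.concatenate([xs, ys])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n = len(xs)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def _perm_tail_probs(pooled: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """All permutation U values for choosing n of len(pooled) as the x-sample."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    us = np.array(
        [
            sum(ranks[list(comb)]) - n * (n + 1) / 2.0
            for comb in itertools.combinations(range(len(pooled)), n)
        ]
    )
    return us, ranks


def mann_whitney_u(
    xs: Sequence[float], ys: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """Mann-Whitney U test of xs against ys; returns (U, p).

    U is the number of (x, y) pairs with x > y, counting ties as half
    (mid-rank convention).  ``alternative='greater'`` asks whether xs tend to
    exceed ys, ``'less'`` the reverse, ``'two_sided'`` either.  The p-value
    is exact — enumeration of the permutation null — whenever n + m <= 20,
    with or without ties; beyond that the normal approximation with tie and
    continuity corrections is used.
    """
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if len(xs) == 0 or len(ys) == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n, m = len(xs), len(ys)
    u = _midrank_u(xs, ys)
    pooled = np.concatenate([xs, ys])
    has_ties = len(np.unique(pooled)) < len(pooled)
    eps = 1e-9

    if n + m <= 20:
        if not has_ties:
            counts = _u_counts(n, m)
            total = counts.sum()
            ui = int(round(u))
            p_greater = counts[ui:].sum() / total
            p_less = counts[: ui + 1].sum() / total
        else:
            us, _ = _perm_tail_probs(pooled, n)
            p_greater = float(np.mean(us >= u - eps))
            p_less = float(np.mean(us <= u + eps))
    else:
        mu = n * m / 2.0
        N = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
        sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            p_greater = p_less = 1.0
        else:
            from scipy.stats import norm

            sigma = np.sqrt(sigma2)
            p_greater = float(norm.sf((u - mu - 0.5) / sigma))
            p_less = float(norm.cdf((u - mu + 0.5) / sigma))

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return u, float(min(1.0, p))


# ------------------------------------------------------------------ comparisons

@dataclass
class FoldScores:
    """Fold-wise F1 samples for one configuration on one task."""

    configuration: Configuration
    f1_per_fold: list[float]

    @property
    def config_id(self) -> str:
        return self.configuration.config_id

    @property
    def mean(self) -> float:
        return float(np.mean(self.f1_per_fold))

    @property
    def std(self) -> float:
        return float(np.std(self.f1_per_fold, ddof=1)) if len(self.f1_per_fold) > 1 else 0.0


@dataclass
class ComparisonResult:
    """One-sided test of whether the weaker candidate underperforms the stronger."""

    task: str
    weaker_config: Configuration
    stronger_config: Configuration
    u_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def comparison_matrix(
    scores: Sequence[FoldScores],
    alpha: float = 0.05,
    holm: bool = False,
    original_version: str = "original",
) -> tuple[list[ComparisonResult], dict]:
    """All pairwise one-sided comparisons within each task.

    For every task and every ordered pair (A, B) of distinct configurations
    on that task, tests whether A (weaker candidate) scores below B (stronger
    candidate): c configurations yield c(c-1) tests per task.  No
    multiple-testing correction is applied by default; ``holm=True`` applies
    a Holm adjustment across all tests.  The summary counts the total tests,
    the significant ones, and the subset where a configuration trained on
    ``original_version`` data beats a pseudonymized sibling.
    """
    by_task: dict[str, list[FoldScores]] = {}
    k_sizes = {len(s.f1_per_fold) for s in scores}
    if len(k_sizes) > 1:
        raise ValidationError(f"inconsistent fold counts across configurations: {k_sizes}")
    for s in scores:
        by_task.setdefault(s.configuration.task, []).append(s)
    results: list[ComparisonResult] = []
    for task, task_scores in by_task.items():
        for a, b in itertools.permutations(task_scores, 2):
            u, p = mann_whitney_u(a.f1_per_fold, b.f1_per_fold, alternative="less")
            results.append(
                ComparisonResult(
                    task=task,
                    weaker_config=a.configuration,
                    stronger_config=b.configuration,
                    u_statistic=u,
                    p_value=p,
                    significant=p < alpha,
                    alpha=alpha,
                )
            )
    if holm:
        adjusted = holm_adjust([r.p_value for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_value = p_adj
            r.significant = p_adj < alpha
    n_sig = sum(r.significant for r in results)
    originals_beating_pseudo = [
        r
        for r in results
        if r.significant
        and r.stronger_config.data_version == original_version
        and r.weaker_config.data_version != original_version
    ]
    summary = {
        "total_tests": len(results),
        "n_significant": n_sig,
        "n_original_beats_pseudonymized": len(originals_beating_pseudo),
        "original_beats_pseudonymized": originals_beating_pseudo,
    }
    return results, summary


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    if not p_values:
        return []
    _, adj, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adj]


def report_tables(
    scores: Sequence[FoldScores],
    comparisons: Sequence[ComparisonResult],
    out_dir=None,
):
    """Score and comparison tables as DataFrames (optionally written to CSV).

    The score table has one row per configuration x task with mean +/- std
    over the folds; the comparison table lists the significant weaker/stronger
    pairs with their p-values.
    """
    import pandas as pd
    from pathlib import Path

    score_rows = [
        {
            "model": s.configuration.model,
            "data_version": s.configuration.data_version,
            "task": s.configuration.task,
            "mean_f1": round(s.mean, 4),
            "std_f1": round(s.std, 4),
            "folds": len(s.f1_per_fold),
        }
        for s in scores
    ]
    score_df = pd.DataFrame(score_rows)
    comp_rows = [
        {
            "task": r.task,
            "weaker_model": r.weaker_config.model,
            "weaker_data": r.weaker_config.data_version,
            "stronger_model": r.stronger_config.model,
            "stronger_data": r.stronger_config.data_version,
            "u": r.u_statistic,
            "p_value": round(r.p_value, 6),
        }
        for r in comparisons
        if r.significant
    ]
    comp_df = pd.DataFrame(
        comp_rows,
        columns=[
            "task", "weaker_model", "weaker_data",
            "stronger_model", "stronger_data", "u", "p_value",
        ],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        score_df.to_csv(out_dir / "scores.csv", index=False)
        comp_df.to_csv(out_dir / "comparisons.csv", index=False)
    return score_df, comp_df


# ------------------------------------------------------------------ executor

def run_experiment(
    plan: ExperimentPlan,
    corpora: Mapping[str, Mapping[str, Sequence[AnnotatedDocument]]],
    task_types: Mapping[str, str] | None = None,
) -> list[FoldScores]:
    """Execute a plan over ``corpora[task][data_version]`` document lists.

    Folds are split on document indices once per task (all data versions of a
    task must be aligned, same length and order), so a pseudonymized
    configuration trains *and* tests on pseudonymized folds while comparisons
    across versions are fold-matched.
    """
    scores: list[FoldScores] = []
    fold_cache: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for task in plan.tasks:
        versions = corpora.get(task)
        if versions is None:
            raise ValidationError(f"no corpora provided for task {task!r}")
        lengths = {v: len(d) for v, d in versions.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(
                f"data versions of task {task!r} are not aligned: {lengths}"
            )
        n = next(iter(lengths.values()))
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed & 0x7FFFFFFF)
        fold_cache[task] = list(splitter.split(np.arange(n)))
    import zlib

    for config in plan.configurations:
        docs = list(corpora[config.task][config.data_version])
        task_type = (task_types or {}).get(config.task, "doc_classification")
        fold_f1 = []
        for fold_i, (train_idx, test_idx) in enumerate(fold_cache[config.task]):
            # per-run training stochasticity, deterministic under plan.seed
            fit_seed = zlib.crc32(
                f"{plan.seed}|{config.config_id}|{fold_i}".encode()
            )
            f1 = train_eval_fold(
                [docs[i] for i in train_idx],
                [docs[i] for i in test_idx],
                task_type,
                model=config.model,
                fit_seed=fit_seed,
            )
            fold_f1.append(f1)
        scores.append(FoldScores(configuration=config, f1_per_fold=fold_f1))
    return scores
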