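"""Two-step epitope biomarker model.

Step 1 is a logistic (binomial GLM, unpenalised) classifier of periodontitis
(P) vs periodontally healthy (H) on the capped epitope features A, B and C,
fit to a stratified 80% training split with 5-fold cross-validated decision
threshold selection (maximising balanced accuracy), validated on the held-out
20%, with AUROC and a seeded bootstrap 95% CI on the training predictions.

Step 2 stratifies ACS vs no-CAD within each periodontal group by a single
">= threshold" rule per epitope feature, with thresholds from ROC analysis
(Youden's J, specificity-favouring tie-break): epitope C in stratum H and
epitope A in stratum G call ACS when high; epitopes A and E in stratum P call
no-CAD when high (combined by OR by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

STEP1_FEATURES = ("A", "B", "C")


def cap_normalize_features(epitope_abundance: pd.DataFrame) -> pd.DataFrame:
    """Normalise each feature by its 97.5th percentile and cap at 1.

    The percentile uses linear interpolation.  A feature whose percentile is
    zero falls back to its maximum; an all-zero feature is an error.
    """
    if len(epitope_abundance) < 2:
        raise ValueError("need >= 2 subjects")
    out = {}
    for name, col in epitope_abundance.items():
        v = col.to_numpy(dtype=float)
        q = float(np.percentile(v, 97.5))
        if q <= 0:
            q = float(v.max())
        if q <= 0:
            raise ValueError(f"feature {name!r} is all-zero")
        out[name] = np.minimum(v / q, 1.0)
    return pd.DataFrame(out, index=epitope_abundance.index)


def balanced_accuracy(predictions, labels) -> float:
    """(sensitivity + specificity) / 2 for binary predictions and labels."""
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    sens = float(p[y].mean())
    spec = float((~p[~y]).mean())
    return (sens + spec) / 2.0


@dataclass
class Step1Model:
    """Fitted logistic periodontitis classifier with its operating threshold."""

    feature_names: tuple
    coef: np.ndarray
    intercept: float
    threshold: float
    train_balanced_accuracy: float
    validation_balanced_accuracy: float
    auroc: float
    auroc_ci: tuple[float, float]
    roc: pd.DataFrame = field(repr=False, default=None)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        z = X @ self.coef + self.intercept
        return expit(z)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(features) >= self.threshold


def _fit_logistic(X: np.ndarray, y: np.ndarray, seed: int) -> LogisticRegression:
    # C=inf: unpenalised maximum-likelihood logistic fit
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(X, y)
    if int(np.max(clf.n_iter_)) >= 2000:
        raise RuntimeError(
            f"logistic fit did not converge in {int(np.max(clf.n_iter_))} iterations; "
            "features may be degenerate"
        )
    return clf


def fit_step1_model(features: pd.DataFrame, labels, split: float = 0.8, folds: int = 5,
                    seed: int = 0, n_bootstrap: int = 2000) -> Step1Model:
    """Fit the step-1 periodontitis-vs-healthy logistic model.

    ``features``: subject x feature abundances (typically A, B, C after
    ``cap_normalize_features``).  ``labels``: 1/True = periodontitis.
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    X = features.to_numpy(dtype=float)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, stratify=y, random_state=seed, shuffle=True
    )
    ytr, yte = y[train_idx], y[test_idx]
    if len(set(ytr)) < 2 or len(set(yte)) < 2:
        raise ValueError("a class is absent from the train or validation split")
    Xtr, Xte = X[train_idx], X[test_idx]

    # out-of-fold probabilities on the training part drive threshold choice
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(ytr))
    for tr, va in skf.split(Xtr, ytr):
        clf = _fit_logistic(Xtr[tr], ytr[tr], seed)
        oof[va] = clf.predict_proba(Xtr[va])[:, 1]
    best_t, best_ba = 0.5, -1.0
    for t in np.unique(oof):
        ba = balanced_accuracy(oof >= t, ytr)
        if ba > best_ba or (ba == best_ba and t > best_t):
            best_t, best_ba = float(t), ba

    final = _fit_logistic(Xtr, ytr, seed)
    ptr = final.predict_proba(Xtr)[:, 1]
    pte = final.predict_proba(Xte)[:, 1]
    ba_train = balanced_accuracy(ptr >= best_t, ytr)
    ba_val = balanced_accuracy(pte >= best_t, yte)

    fpr, tpr, thr = roc_curve(ytr, ptr)
    auroc = float(roc_auc_score(ytr, ptr))
    rng = np.random.default_rng(seed)
    boots = []
    while len(boots) < n_bootstrap:
        b = rng.integers(0, len(ytr), len(ytr))
        if len(set(ytr[b])) < 2:
            continue
        boots.append(roc_auc_score(ytr[b], ptr[b]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return Step1Model(
        feature_names=tuple(features.columns),
        coef=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        threshold=best_t,
        train_balanced_accuracy=ba_train,
        validation_balanced_accuracy=ba_val,
        auroc=auroc,
        auroc_ci=(float(lo), float(hi)),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
    )


def cross_validated_auroc(features: pd.DataFrame, labels, folds: int = 5,
                          seed: int = 0) -> float:
    """AUROC of out-of-fold logistic predictions (stratified k-fold).

    Unlike the training AUROC this is not optimistically biased, so it is the
    right quantity for permutation/null calibration checks.
    """
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for tr, va in skf.split(X, y):
        clf = _fit_logistic(X[tr], y[tr], seed)
        oof[va] = clf.predict_proba(X[va])[:, 1]
    return float(roc_auc_score(y, oof))


@dataclass
class RocResult:
    threshold: float
    sensitivity: float
    specificity: float
    auroc: float
    candidates: pd.DataFrame = field(repr=False, default=None)


def roc_threshold(values, labels, direction: str = "ge") -> RocResult:
    """ROC threshold for a single feature: sweep observed values, maximise
    Youden's J (ties favour specificity, then the more stringent threshold).

    ``direction='ge'``: value >= threshold calls positive; ``'le'``: value <=
    threshold calls positive.
    """
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    rows = []
    for t in np.unique(v):
        pred = v >= t if direction == "ge" else v <= t
        sens = float(pred[y].mean())
        spec = float((~pred[~y]).mean())
        rows.append((float(t), sens, spec, sens + spec - 1.0))
    cand = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden_j"])
    stringent = 1.0 if direction == "ge" else -1.0
    best = max(rows, key=lambda r: (r[3], r[2], stringent * r[0]))
    score = v if direction == "ge" else -v
    return RocResult(
        threshold=best[0],
        sensitivity=best[1],
        specificity=best[2],
        auroc=float(roc_auc_score(y.astype(int), score)),
        candidates=cand,
    )


@dataclass
class Step2Rule:
    """One '>= threshold' rule inside a periodontal stratum."""

    feature: str
    direction: str  # 'ge' or 'le'
    threshold: float
    call_if_positive: str  # 'ACS' or 'noCAD'
    sensitivity: float
    specificity: float
    auroc: float

    def fires(self, value: float) -> bool:
        return value >= self.threshold if self.direction == "ge" else value <= self.threshold


# which epitope feature marks which CAD phenotype per periodontal stratum
STEP2_DESIGN = {
    "H": [("C", "ACS")],
    "G": [("A", "ACS")],
    "P": [("A", "noCAD"), ("E", "noCAD")],
}


@dataclass
class TwoStepModel:
    step1: Step1Model
    step2: dict[str, list[Step2Rule]]
    stratum_p_logic: str = "or"


def fit_step2_rules(features: pd.DataFrame, cad_labels: pd.Series,
                    perio_groups: pd.Series,
                    design: dict | None = None) -> dict[str, list[Step2Rule]]:
    """Per-stratum ROC thresholds for ACS vs no-CAD.

    ``cad_labels`` must be 'ACS' / 'noCAD' (s-CAD subjects are excluded);
    ``perio_groups`` 'H'/'G'/'P'.
    """
    design = design or STEP2_DESIGN
    rules: dict[str, list[Step2Rule]] = {}
    for stratum, specs in design.items():
        mask = (perio_groups == stratum) & cad_labels.isin(["ACS", "noCAD"])
        sub = features.loc[mask]
        lab = cad_labels.loc[mask]
        rules[stratum] = []
        for feat, marks in specs:
            pos = (lab == marks).to_numpy()
            res = roc_threshold(sub[feat].to_numpy(), pos, direction="ge")
            rules[stratum].append(Step2Rule(
                feature=feat, direction="ge", threshold=res.threshold,
                call_if_positive=marks, sensitivity=res.sensitivity,
                specificity=res.specificity, auroc=res.auroc,
            ))
    return rules


def two_step_classify(model: TwoStepModel, features: pd.Series | dict,
                      perio_group: str | None = None) -> tuple[str, str]:
    """Classify one subject: periodontal call (P vs H), then the CAD call
    (ACS vs noCAD) with the assigned stratum's rule(s).

    ``perio_group`` overrides step 1 when the true stratum (e.g. G) is known.
    """
    feats = pd.Series(features, dtype=float)
    if perio_group is None:
        row = feats.to_frame().T
        perio_group = "P" if bool(model.step1.predict(row)[0]) else "H"
    rules = model.step2.get(perio_group)
    if not rules:
        raise ValueError(f"no step-2 rule for stratum {perio_group!r}")
    fired = [r.call_if_positive for r in rules if r.fires(float(feats[r.feature]))]
    if len(rules) == 1:
        cad = rules[0].call_if_positive if fired else ("noCAD" if rules[0].call_if_positive == "ACS" else "ACS")
    else:
        target = rules[0].call_if_positive  # the marked phenotype, e.g. noCAD in P
        other = "ACS" if target == "noCAD" else "noCAD"
        if model.stratum_p_logic == "or":
            cad = target if fired else other
        else:  # 'and'
            cad = target if len(fired) == len(rules) else other
    return perio_group, cad


def fit_two_step(features: pd.DataFrame, perio_groups: pd.Series, cad_labels: pd.Series,
                 seed: int = 0, split: float = 0.8, folds: int = 5,
                 n_bootstrap: int = 2000, stratum_p_logic: str = "or") -> TwoStepModel:
    """Fit the full two-step model from epitope features A..E and labels."""
    ph = perio_groups.isin(["P", "H"])
    step1 = fit_step1_model(
        features.loc[ph, list(STEP1_FEATURES)],
        (perio_groups.loc[ph] == "P").to_numpy(dtype=int),
        split=split, folds=folds, seed=seed, n_bootstrap=n_bootstrap,
    )
    step2 = fit_step2_rules(features, cad_labels, perio_groups)
    return TwoStepModel(step1=step1, step2=step2, stratum_p_logic=stratum_p_logic)
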