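"""Downstream statistics: dose-response fits, temporal-order recovery,
programme-feature PCA and classification, differential recorder activity,
and factorial experiment-design accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

from ._util import derive_seed
from .codec import CountTable
from .programmes import AgonistChannel, SignalProgramme, enumerate_programmes
from .simulate import ReadModel, SimConfig, TapeSpec, generate_reads, simulate_tapes
from .tape import (
    TapeReference,
    bigram_log_ratio,
    encode_programme_features,
    feature_names,
    parse_tape_read,
    summarize_grams,
)


class FitError(RuntimeError):
    """Dose-response fit failed to converge or the response is flat."""


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of edited fraction versus agonist dose."""

    ec50: float
    hill_n: float
    floor: float
    ceiling: float
    residual: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.floor >= self.ceiling:
            raise ValueError("floor must be below ceiling")

    def predict(self, doses: Sequence[float]) -> np.ndarray:
        return _four_pl(np.asarray(doses, float), self.floor, self.ceiling,
                        self.ec50, self.hill_n)


def _four_pl(dose: np.ndarray, floor: float, ceiling: float,
             ec50: float, hill_n: float) -> np.ndarray:
    """Hill-form logistic; exactly ``floor`` at dose 0 (sigmoid in log-dose
    elsewhere)."""
    dose = np.asarray(dose, float)
    out = np.full(dose.shape, floor, dtype=float)
    pos = dose > 0
    ratio = (ec50 / dose[pos]) ** hill_n
    out[pos] = floor + (ceiling - floor) / (1.0 + ratio)
    return out


def fit_dose_response(doses: Sequence[float], edited_fractions: Sequence[float],
                      min_dynamic_range: float = 1e-4) -> DoseResponseFit:
    """Nonlinear least-squares four-parameter logistic fit on log-dose.

    Multi-start over a grid of EC50 (geometric over the positive dose range)
    and Hill-coefficient initialisations; returns the best-converged fit.
    A flat response (dynamic range below ``min_dynamic_range``) or universal
    non-convergence raises :class:`FitError`.
    """
    doses = np.asarray(doses, float)
    y = np.asarray(edited_fractions, float)
    if len(doses) < 5:
        raise ValueError("need at least 5 dose points")
    if y.max() - y.min() < min_dynamic_range:
        raise FitError("flat response: ceiling indistinguishable from floor")
    pos = doses[doses > 0]
    ec50_starts = np.geomspace(pos.min(), pos.max(), 5)
    best = None
    for ec50_0, hill_0 in product(ec50_starts, (0.5, 1.0, 2.0, 4.0)):
        p0 = [max(y.min(), 0.0), y.max(), ec50_0, hill_0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _four_pl, doses, y, p0=p0, maxfev=20_000,
                    bounds=([0, 0, pos.min() / 100, 0.05],
                            [1, 1.5, pos.max() * 100, 20]),
                )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((_four_pl(doses, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError("no start converged")
    (floor, ceiling, ec50, hill_n), resid = best
    if ceiling - floor < min_dynamic_range:
        raise FitError("fitted dynamic range is negligible")
    return DoseResponseFit(ec50=float(ec50), hill_n=float(hill_n),
                           floor=float(floor), ceiling=float(ceiling),
                           residual=resid)


def decode_sample(programme: SignalProgramme, channels: Sequence[AgonistChannel],
                  spec: TapeSpec, config: SimConfig, read_model: ReadModel,
                  read_seed: int):
    """Simulate one sample end to end (tapes -> reads -> parses) and return
    its gram summary."""
    tapes = simulate_tapes(programme, channels, spec, config)
    reads = generate_reads(tapes, spec, read_model, seed=read_seed, as_strings=True)
    ref = TapeReference(spec)
    parsed = (parse_tape_read(r, ref) for r in reads)
    return summarize_grams(parsed, spec)


def order_recovery_experiment(channels: Sequence[AgonistChannel], spec: TapeSpec,
                              config: SimConfig, seeds: Sequence[int],
                              read_model: ReadModel | None = None,
                              programmes: Sequence[SignalProgramme] | None = None,
                              pseudocount: float = 0.5) -> pd.DataFrame:
    """Run every serial/layered programme through the full pipeline per seed
    and score whether the replicate-mean bigram log2-ratio sign identifies
    the first-applied channel.

    Returns one row per programme x replicate with the ratio, plus
    ``sign_correct`` computed on the replicate mean (constant within a
    programme).
    """
    if len(channels) != 2:
        raise ValueError("order recovery is defined for two channels")
    if read_model is None:
        read_model = ReadModel()
    if programmes is None:
        programmes = [p for p in enumerate_programmes(total_days=6.0)
                      if p.pattern in ("serial", "layered")]
    ch_by_name = {c.name: c for c in channels}
    rows = []
    for prog in programmes:
        ratios = []
        for seed in seeds:
            cfg = replace(config, seed=derive_seed(seed, prog.label))
            summary = decode_sample(prog, channels, spec, cfg, read_model,
                                    read_seed=derive_seed(seed, prog.label + "/reads"))
            first = ch_by_name[prog.first_channel].symbol_id
            second = next(c.symbol_id for c in channels if c.symbol_id != first)
            ratios.append(bigram_log_ratio(summary, first, second,
                                           pseudocount=pseudocount))
        mean_ratio = float(np.mean(ratios))
        for seed, ratio in zip(seeds, ratios):
            rows.append({
                "programme": prog.label, "pattern": prog.pattern,
                "first_channel": prog.first_channel, "replicate_seed": seed,
                "bigram_log_ratio": ratio, "replicate_mean_ratio": mean_ratio,
                "sign_correct": mean_ratio > 0,
            })
    return pd.DataFrame(rows)


@dataclass
class ProgrammeFeatureMatrix:
    """Rows = samples (programme x replicate), columns = the unigram/bigram
    programme-feature encoding."""

    values: np.ndarray
    labels: list[str]
    replicate_ids: list[int]
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("matrix shape inconsistent with labels/features")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")


def programme_feature_matrix(programmes: Sequence[SignalProgramme],
                             channels: Sequence[AgonistChannel], spec: TapeSpec,
                             config: SimConfig, read_model: ReadModel,
                             seeds: Sequence[int]) -> ProgrammeFeatureMatrix:
    """Simulate each programme once per replicate seed and encode its gram
    summary into the fixed programme-feature ordering."""
    rows, labels, reps = [], [], []
    for prog in programmes:
        for seed in seeds:
            cfg = replace(config, seed=derive_seed(seed, "feat/" + prog.label))
            summary = decode_sample(
                prog, channels, spec, cfg, read_model,
                read_seed=derive_seed(seed, "feat/" + prog.label + "/reads"))
            rows.append(encode_programme_features(summary, spec))
            labels.append(prog.label)
            reps.append(seed)
    return ProgrammeFeatureMatrix(values=np.vstack(rows), labels=labels,
                                  replicate_ids=reps,
                                  feature_names=feature_names(spec))


def pca_embed(matrix: ProgrammeFeatureMatrix, n_components: int = 3,
              scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Centred (optionally unit-variance-scaled) PCA of the feature matrix.

    Constant columns are dropped with a warning before scaling. Returns
    (scores, explained-variance fractions).
    """
    X = matrix.values
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components rows")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant feature columns")
        X = X[:, keep]
    if scale:
        X = StandardScaler().fit_transform(X)
    else:
        X = X - X.mean(axis=0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def classify_programmes(matrix: ProgrammeFeatureMatrix, seed: int = 0,
                        n_estimators: int = 300) -> tuple[float, pd.DataFrame]:
    """Leave-one-replicate-out random-forest classification of programmes.

    Each fold holds out every sample of one replicate id; accuracy is the
    mean over folds. Returns (mean accuracy, confusion table).
    """
    reps = np.asarray(matrix.replicate_ids)
    labels = np.asarray(matrix.labels)
    classes = sorted(set(matrix.labels))
    if len(set(matrix.replicate_ids)) < 2:
        raise ValueError("need >= 2 replicates per label for held-out folds")
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    accs = []
    for fold_rep in sorted(set(matrix.replicate_ids)):
        test = reps == fold_rep
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=derive_seed(seed, f"rf/{fold_rep}"))
        clf.fit(matrix.values[~test], labels[~test])
        pred = clf.predict(matrix.values[test])
        accs.append(float(np.mean(pred == labels[test])))
        for truth, hat in zip(labels[test], pred):
            confusion.loc[truth, hat] += 1
    return float(np.mean(accs)), confusion


def differential_activity(counts_a: Sequence[CountTable],
                          counts_b: Sequence[CountTable],
                          lfc_threshold: float = 1.0, alpha: float = 0.001,
                          pseudocount: float = 0.5) -> pd.DataFrame:
    """Differentially active recorders between two replicated conditions.

    Per symbol: log2 ratio of mean edited-read proportions (A over B) and a
    two-sided test on per-replicate log2 proportions (Welch t when both
    conditions have >= 3 replicates, else a pooled normal approximation),
    Benjamini-Hochberg corrected. A call requires adjusted p < ``alpha``
    and |LFC| > ``lfc_threshold``. Symbols absent from every replicate of
    one condition are excluded with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    symbols = sorted(set().union(*(t.counts for t in counts_a + counts_b)))

    def log_props(tables: Sequence[CountTable], sym: str) -> np.ndarray:
        return np.array([
            np.log2((t.counts.get(sym, 0) + pseudocount)
                    / (t.edited_total + pseudocount))
            for t in tables
        ])

    rows = []
    for sym in symbols:
        if (all(t.counts.get(sym, 0) == 0 for t in counts_a)
                and all(t.counts.get(sym, 0) == 0 for t in counts_b)):
            continue
        if (all(t.counts.get(sym, 0) == 0 for t in counts_a)
                or all(t.counts.get(sym, 0) == 0 for t in counts_b)):
            warnings.warn(f"symbol {sym!r} absent from one condition; excluded")
            continue
        la, lb = log_props(counts_a, sym), log_props(counts_b, sym)
        lfc = float(la.mean() - lb.mean())
        if len(la) >= 3 and len(lb) >= 3:
            p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
        else:
            se = np.sqrt(la.var(ddof=1) / len(la) + lb.var(ddof=1) / len(lb))
            z = lfc / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
        rows.append({"symbol": sym, "log2_fold_change": lfc, "p_value": p})
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(adjusted_p=[], called=[])
    result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["called"] = (result["adjusted_p"] < alpha) & (
        result["log2_fold_change"].abs() > lfc_threshold
    )
    return result


def condition_grid(levels_per_channel: Mapping[str, Sequence[float]],
                   n_replicates: int = 3) -> pd.DataFrame:
    """Enumerate a full-factorial exposure design: every combination of the
    per-channel levels, replicated.

    Three agonists at three concentrations in triplicate gives 81 rows;
    three agonists present/absent in triplicate gives 24.
    """
    names = list(levels_per_channel)
    rows = []
    for combo in product(*(levels_per_channel[n] for n in names)):
        for rep in range(1, n_replicates + 1):
            row = dict(zip(names, combo))
            row["replicate"] = rep
            rows.append(row)
    return pd.DataFrame(rows)
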