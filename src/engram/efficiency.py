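"""Sequence/structure prediction of barcode insertion efficiency.

Which barcode a recorder writes biases its write efficiency; this module
predicts a barcode's plasmid-normalised editing score from (i) one-hot
single-nucleotide and dinucleotide content of the k-mer and (ii) a folding
stability feature of the assembled pegRNA carrying the insertion, via an
L1-penalised linear model with cross-validated penalty selection.

The folder is a transparent Nussinov base-pair-maximisation dynamic
programme (GC/AU/GU pair weights, minimum hairpin loop of 3), returning a
pseudo-energy equal to minus the optimal pair score; any external folder
returning real free energies can be plugged in, since the model only
consumes a monotone min-max rescaling of the values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from ._util import BASES, check_nucleotides, derive_seed

PAIR_SCORES = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
               ("G", "U"): 1, ("U", "G"): 1}
MIN_LOOP = 3  # unpaired bases required inside a hairpin
RESCALE_EPS = 1e-6

DINUCLEOTIDES = [a + b for a in BASES for b in BASES]


@dataclass(frozen=True)
class PegRNADesign:
    """Prime-editing guide template with an insertion slot.

    The RT template carries a run of ``N`` marking where the insertional
    barcode goes; the assembled molecule is
    spacer + scaffold + RT template + PBS. The shipped default is a
    synthetic stand-in template (the real scaffold is not bundled).
    """

    spacer: str
    scaffold: str
    rt_template_with_slot: str
    pbs: str

    def __post_init__(self) -> None:
        for part in (self.spacer, self.scaffold, self.pbs):
            check_nucleotides(part)
        check_nucleotides(self.rt_template_with_slot, alphabet="ACGTN")
        slot = self.rt_template_with_slot.count("N")
        if slot == 0 or "N" * slot not in self.rt_template_with_slot:
            raise ValueError("RT template must contain one contiguous N-run slot")

    @property
    def slot_len(self) -> int:
        return self.rt_template_with_slot.count("N")


def default_template(slot_len: int = 5) -> PegRNADesign:
    """Synthetic stand-in pegRNA template: the RT template places the
    insertion slot adjacent to sequence complementary to the spacer, so
    slot content can pair with (and occlude) the spacer."""
    spacer = "GGCCCAGACTGAGCACGTGA"
    return PegRNADesign(
        spacer=spacer,
        scaffold="GTTTAAGAGCTATGCTGGAAACAGCA",
        rt_template_with_slot="TCTGCCATCA" + "N" * slot_len + "CGTGCTCAGTCTG",
        pbs="GGCCCAGACTGAG"[:10],
    )


def assemble_pegrna(insertion: str, template: PegRNADesign) -> str:
    """Substitute an insertion into the template slot and concatenate parts."""
    if len(insertion) != template.slot_len:
        raise ValueError(
            f"insertion length {len(insertion)} != slot length {template.slot_len}"
        )
    check_nucleotides(insertion)
    rt = template.rt_template_with_slot.replace("N" * template.slot_len, insertion)
    return template.spacer + template.scaffold + rt + template.pbs


def fold_mfe(sequence: str) -> float:
    """Pseudo minimum free energy by Nussinov base-pair maximisation.

    Dynamic programme over DNA/RNA ({A,C,G,T/U}); returns minus the maximal
    weighted pair count (GC=3, AU=2, GU=1), with pairs closing a loop of at
    least ``MIN_LOOP`` unpaired bases. Deterministic, 0 for unpairable
    sequences.
    """
    seq = sequence.upper().replace("T", "U")
    check_nucleotides(seq, alphabet="ACGU")
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                w = PAIR_SCORES.get((seq[k], seq[j]))
                if w:
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + w + dp[k + 1][j - 1]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return -float(dp[0][n - 1])


def rescale_mfe(energies: Sequence[float],
                bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Affine min-max map of energies onto (0, 1): the most negative (most
    stable) value maps near 0. ``bounds`` fixes (min, max) externally so a
    prediction-time rescale can reuse the training range."""
    e = np.asarray(energies, dtype=float)
    lo, hi = bounds if bounds is not None else (e.min(), e.max())
    if hi <= lo:
        raise ValueError("energies must span at least two distinct values")
    scaled = RESCALE_EPS + (1 - 2 * RESCALE_EPS) * (e - lo) / (hi - lo)
    return np.clip(scaled, RESCALE_EPS, 1 - RESCALE_EPS)


def encode_sequence_features(barcode: str) -> np.ndarray:
    """One-hot sequence block: 4k single-nucleotide indicators (positions
    outer, A/C/G/T inner) then 16(k-1) dinucleotide indicators — 84 binary
    features for a 5-mer."""
    check_nucleotides(barcode.upper())
    bc = barcode.upper()
    k = len(bc)
    single = np.zeros(4 * k)
    for p, base in enumerate(bc):
        single[4 * p + BASES.index(base)] = 1.0
    di = np.zeros(16 * (k - 1))
    for p in range(k - 1):
        di[16 * p + DINUCLEOTIDES.index(bc[p : p + 2])] = 1.0
    return np.concatenate([single, di])


def sequence_feature_names(k: int = 5) -> list[str]:
    names = [f"pos{p + 1}_{b}" for p in range(k) for b in BASES]
    names += [f"dipos{p + 1}_{d}" for p in range(k - 1) for d in DINUCLEOTIDES]
    return names


def build_feature_matrix(barcodes: Sequence[str],
                         template: PegRNADesign | None = None,
                         folder: Callable[[str], float] = fold_mfe,
                         mfe_bounds: tuple[float, float] | None = None,
                         ) -> tuple[np.ndarray, tuple[float, float]]:
    """Full feature matrix (sequence block + rescaled folding stability of
    the assembled pegRNA) for a set of barcodes.

    Returns the matrix and the (min, max) energy bounds used for rescaling,
    so a fitted model can encode new barcodes on the training scale.
    """
    if template is None:
        template = default_template(len(barcodes[0]))
    seq_block = np.vstack([encode_sequence_features(b) for b in barcodes])
    energies = np.array([folder(assemble_pegrna(b, template)) for b in barcodes])
    if mfe_bounds is None:
        mfe_bounds = (float(energies.min()), float(energies.max()))
    structure = rescale_mfe(energies, bounds=mfe_bounds)
    return np.hstack([seq_block, structure[:, None]]), mfe_bounds


@dataclass
class EfficiencyModel:
    """Fitted L1-penalised linear model over the barcode feature encoding."""

    weights: np.ndarray
    intercept: float
    penalty: float
    cv_folds: int
    feature_names: list[str]
    mfe_bounds: tuple[float, float]
    template: PegRNADesign

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights length must match feature count")

    @property
    def mfe_weight(self) -> float:
        return float(self.weights[-1])


def fit_lasso_cv(X: np.ndarray, y: np.ndarray, folds: int = 10,
                 train_fraction: float = 0.7, seed: int = 0,
                 template: PegRNADesign | None = None,
                 feature_names: Sequence[str] | None = None,
                 mfe_bounds: tuple[float, float] = (0.0, 1.0),
                 ) -> tuple[EfficiencyModel, dict]:
    """Train/test split + lasso with CV-selected penalty on the training set.

    The penalty grid is 50 log-spaced values over ``[1e-4, 10] * sd(y)``;
    the model refits at the CV-optimal penalty and predicts the held-out
    split. Returns the model and a dict with held-out indices, predictions
    and Pearson correlation. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) response")
    rng = np.random.default_rng(derive_seed(seed, "lasso-split"))
    n = len(y)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    alphas = np.logspace(-4, 1, 50) * np.std(y)
    cv = KFold(n_splits=folds, shuffle=True,
               random_state=derive_seed(seed, "lasso-cv"))
    model = LassoCV(alphas=alphas, cv=cv, max_iter=50_000)
    model.fit(X[train_idx], y[train_idx])
    y_hat = model.predict(X[test_idx])
    if len(test_idx) >= 2 and np.std(y_hat) > 0:
        r = float(np.corrcoef(y[test_idx], y_hat)[0, 1])
    else:
        r = float("nan")
    if feature_names is None:
        k = (X.shape[1] - 1 + 16) // 20  # invert 4k + 16(k-1) + 1
        feature_names = sequence_feature_names(k) + ["rescaled_mfe"]
    fitted = EfficiencyModel(
        weights=np.asarray(model.coef_), intercept=float(model.intercept_),
        penalty=float(model.alpha_), cv_folds=folds,
        feature_names=list(feature_names), mfe_bounds=mfe_bounds,
        template=template if template is not None else default_template(),
    )
    report = {"test_idx": test_idx, "predictions": y_hat,
              "observed": y[test_idx], "pearson_r": r,
              "train_idx": train_idx}
    return fitted, report


def predict_scores(model: EfficiencyModel, barcodes: Sequence[str],
                   template: PegRNADesign | None = None,
                   folder: Callable[[str], float] = fold_mfe) -> np.ndarray:
    """Predict editing scores for new barcodes with the training-time
    feature pipeline (training MFE rescale bounds are reused)."""
    if model.weights is None:
        raise RuntimeError("model is not fitted")
    if template is None:
        template = model.template
    X, _ = build_feature_matrix(barcodes, template=template, folder=folder,
                                mfe_bounds=model.mfe_bounds)
    return X @ model.weights + model.intercept


def lasso_at_penalty(X: np.ndarray, y: np.ndarray, alpha: float) -> Lasso:
    """Plain lasso fit at a fixed penalty (limit checks, diagnostics)."""
    m = Lasso(alpha=alpha, max_iter=50_000)
    m.fit(np.asarray(X, float), np.asarray(y, float))
    return m
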