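"""Copy-number signatures and the chromothripsis score (CPS).

Pipeline: six per-sample CN feature distributions -> per-feature
Gaussian-mixture categorization (BIC-selected component count) ->
sample x category count matrix -> non-negative signature extraction
(restarted multiplicative-update NMF, KL divergence) -> logistic GLM on
signature exposures, whose predicted probability of chromothripsis is
the CPS. Exposed statsmodels-style: build a
:class:`ChromothripsisScoreModel`, call :meth:`fit`, get a
:class:`CPSResults` carrying estimates, the cross-validated AUC,
``summary()``, ``predict()`` and JSON persistence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls
from scipy.special import expit
from sklearn.decomposition import NMF
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

from .cn_profile import CNProfile, breakpoints

__all__ = [
    "CNFeatureVectors",
    "FEATURE_NAMES",
    "extract_cn_features",
    "CategoryModel",
    "categorize_features",
    "extract_signatures",
    "select_n_signatures",
    "ChromothripsisScoreModel",
    "CPSResults",
    "fit_cps_model",
    "score_cps",
]

FEATURE_NAMES = (
    "segment_size",
    "absolute_cn",
    "cn_change",
    "breakpoints_per_arm",
    "oscillation_chain_lengths",
    "breakpoints_per_10mb",
)

BIN_WIDTH = 10_000_000  # "breakpoints per 10 Mb", tiled from position 1
MIN_CHAIN = 3


@dataclass
class CNFeatureVectors:
    """Six per-sample CN feature value lists."""

    sample_id: str
    segment_size: np.ndarray
    absolute_cn: np.ndarray
    cn_change: np.ndarray
    breakpoints_per_arm: np.ndarray
    oscillation_chain_lengths: np.ndarray
    breakpoints_per_10mb: np.ndarray

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _chain_lengths(cn: list[int]) -> list[int]:
    """Lengths of all maximal two-state alternating runs (>= MIN_CHAIN)."""
    out: list[int] = []
    chain = 1
    for i in range(1, len(cn)):
        if cn[i] == cn[i - 1]:
            if chain >= MIN_CHAIN:
                out.append(chain)
            chain = 1
        elif chain >= 2 and cn[i] == cn[i - 2]:
            chain += 1
        else:
            if chain >= MIN_CHAIN:
                out.append(chain)
            chain = 2
    if chain >= MIN_CHAIN:
        out.append(chain)
    return out


def extract_cn_features(profile: CNProfile) -> CNFeatureVectors:
    """Compute the six CN feature distributions for one (filtered) profile.

    Arm and 10-Mb-bin breakpoint counts cover every arm/bin of each
    chromosome with any segment, zeros included; terminal partial bins
    are kept un-normalised.
    """
    by_chrom = profile.by_chromosome()
    bps = breakpoints(profile)
    bp_pos: dict[str, list[int]] = {}
    for bp in bps:
        bp_pos.setdefault(bp.chromosome, []).append(bp.position)

    sizes, cns, changes, per_arm, chains, per_bin = [], [], [], [], [], []
    for chrom, segs in by_chrom.items():
        sizes.extend(s.length for s in segs)
        cns.extend(s.copy_number for s in segs)
        seq = [s.copy_number for s in segs]
        changes.extend(abs(b - a) for a, b in zip(seq, seq[1:]) if a != b)
        chains.extend(_chain_lengths(seq))
        positions = np.asarray(bp_pos.get(chrom, []), dtype=int)
        for _, astart, aend in profile.genome.arms(chrom):
            per_arm.append(int(np.count_nonzero((positions >= astart) & (positions <= aend))))
        length = profile.genome.lengths.get(chrom, max(s.end for s in segs))
        n_bins = int(np.ceil(length / BIN_WIDTH))
        counts = np.bincount((positions - 1) // BIN_WIDTH, minlength=n_bins)
        per_bin.extend(int(c) for c in counts[:n_bins])

    return CNFeatureVectors(
        sample_id=profile.sample_id,
        segment_size=np.asarray(sizes, dtype=float),
        absolute_cn=np.asarray(cns, dtype=float),
        cn_change=np.asarray(changes, dtype=float),
        breakpoints_per_arm=np.asarray(per_arm, dtype=float),
        oscillation_chain_lengths=np.asarray(chains, dtype=float),
        breakpoints_per_10mb=np.asarray(per_bin, dtype=float),
    )


# ---------------------------------------------------------------------------
# categorization


@dataclass
class _FeatureMixture:
    feature: str
    log_transform: bool
    means: np.ndarray        # sorted ascending
    variances: np.ndarray
    weights: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.means)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Maximum-posterior component index for each value."""
        if self.n_components == 1:
            return np.zeros(len(values), dtype=int)
        x = np.log10(values) if self.log_transform else values
        x = np.asarray(x, dtype=float)[:, None]
        log_dens = (
            -0.5 * np.log(2 * np.pi * self.variances)
            - 0.5 * (x - self.means) ** 2 / self.variances
            + np.log(self.weights)
        )
        return np.argmax(log_dens, axis=1)


@dataclass
class CategoryModel:
    """Frozen per-feature mixtures plus the category registry."""

    mixtures: dict[str, _FeatureMixture]
    registry: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.registry:
            col = 0
            for feat in FEATURE_NAMES:
                for k in range(self.mixtures[feat].n_components):
                    self.registry[f"{feat}_{k}"] = col
                    col += 1

    @property
    def n_categories(self) -> int:
        return len(self.registry)

    @property
    def category_names(self) -> list[str]:
        return sorted(self.registry, key=self.registry.get)

    def transform(self, vectors: list[CNFeatureVectors]) -> pd.DataFrame:
        """Tally events into categories: samples x categories counts."""
        mat = np.zeros((len(vectors), self.n_categories), dtype=int)
        for i, fv in enumerate(vectors):
            for feat in FEATURE_NAMES:
                values = fv.feature(feat)
                if len(values) == 0:
                    continue
                comps = self.mixtures[feat].assign(values)
                for k in comps:
                    mat[i, self.registry[f"{feat}_{k}"]] += 1
        return pd.DataFrame(
            mat, index=[fv.sample_id for fv in vectors], columns=self.category_names
        )

    def to_dict(self) -> dict:
        return {
            "registry": self.registry,
            "mixtures": {
                f: {
                    "log_transform": m.log_transform,
                    "means": m.means.tolist(),
                    "variances": m.variances.tolist(),
                    "weights": m.weights.tolist(),
                }
                for f, m in self.mixtures.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryModel":
        mixtures = {
            f: _FeatureMixture(
                feature=f,
                log_transform=m["log_transform"],
                means=np.asarray(m["means"]),
                variances=np.asarray(m["variances"]),
                weights=np.asarray(m["weights"]),
            )
            for f, m in d["mixtures"].items()
        }
        return cls(mixtures=mixtures, registry={k: int(v) for k, v in d["registry"].items()})


def _fit_mixture(values: np.ndarray, feature: str, max_components: int, seed: int) -> _FeatureMixture:
    log_transform = feature == "segment_size"
    x = np.log10(values) if log_transform else values.astype(float)
    distinct = np.unique(x)
    if distinct.size < 2:
        mean = distinct[0] if distinct.size else 0.0
        return _FeatureMixture(feature, log_transform, np.array([mean]),
                               np.array([1e-6]), np.array([1.0]))
    best, best_bic = None, np.inf
    kmax = min(max_components, distinct.size)
    data = x[:, None]
    for k in range(2, kmax + 1):
        for cov in ("tied", "full"):  # equal-variance and free-variance families
            gm = GaussianMixture(
                n_components=k, covariance_type=cov, random_state=seed,
                reg_covar=1e-4, max_iter=200, n_init=1,
            )
            try:
                gm.fit(data)
            except ValueError:
                continue
            bic = gm.bic(data)
            if bic < best_bic:
                best_bic, best = bic, gm
    if best is None:  # fall back to a single category
        return _FeatureMixture(feature, log_transform, np.array([float(x.mean())]),
                               np.array([float(x.var()) + 1e-6]), np.array([1.0]))
    means = best.means_.ravel()
    if best.covariance_type == "tied":
        variances = np.full(best.n_components, float(np.ravel(best.covariances_)[0]))
    else:
        variances = best.covariances_.ravel()
    order = np.argsort(means)
    return _FeatureMixture(
        feature, log_transform, means[order], variances[order], best.weights_[order]
    )


def categorize_features(
    vectors: list[CNFeatureVectors],
    max_components: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, CategoryModel]:
    """Fit per-feature mixtures on the pooled cohort and tally counts.

    Each feature's values are pooled across samples and fit with
    univariate Gaussian mixtures (segment size on log10 scale) for 2 to
    ``max_components`` components in both equal- and free-variance
    families; the BIC-best fit defines the categories. Every event is
    assigned to its maximum-posterior component. Features with fewer
    than two distinct values collapse to a single forced category.
    """
    if len(vectors) < 20:
        warnings.warn(f"categorizing only {len(vectors)} samples; >= 20 recommended",
                      stacklevel=2)
    mixtures = {}
    for feat in FEATURE_NAMES:
        pooled = np.concatenate([fv.feature(feat) for fv in vectors]) if vectors else np.array([])
        if pooled.size == 0 or np.unique(pooled).size < 2:
            if pooled.size and np.unique(pooled).size < 2:
                warnings.warn(f"feature {feat} is constant; single category", stacklevel=2)
            mean = float(pooled[0]) if pooled.size else 0.0
            mixtures[feat] = _FeatureMixture(feat, feat == "segment_size",
                                             np.array([mean]), np.array([1e-6]), np.array([1.0]))
        else:
            mixtures[feat] = _fit_mixture(pooled, feat, max_components, seed)
    model = CategoryModel(mixtures=mixtures)
    return model.transform(vectors), model


# ---------------------------------------------------------------------------
# signature extraction


def extract_signatures(
    matrix: pd.DataFrame | np.ndarray,
    n_signatures: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative signature decomposition of a category count matrix.

    Restarted multiplicative-update NMF under KL divergence; the restart
    with the lowest objective is kept. Returns ``(signatures, exposures)``
    with signatures of shape (categories, K), columns on the simplex,
    and exposures of shape (samples, K) scaled so that
    ``exposures @ signatures.T`` reconstructs the matrix.
    """
    M = np.asarray(matrix, dtype=float)
    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    if n_signatures > M.shape[1]:
        raise ValueError("more signatures requested than categories")
    # KL-NMF is undefined on all-zero rows/columns; lift by epsilon
    M = np.where(M == 0, 1e-9, M)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_err, best_W, best_H = np.inf, None, None
    for rs in child_seeds:
        model = NMF(
            n_components=n_signatures, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=int(rs % (2**31)), max_iter=max_iter, tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(M)
        if model.reconstruction_err_ < best_err:
            best_err, best_W, best_H = model.reconstruction_err_, W, model.components_
    scale = best_H.sum(axis=1)  # per-signature mass
    signatures = (best_H / scale[:, None]).T  # categories x K, simplex columns
    exposures = best_W * scale[None, :]
    return signatures, exposures


def _match_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Mean cosine similarity of columns of a and b under optimal matching."""
    from scipy.optimize import linear_sum_assignment

    an = a / np.linalg.norm(a, axis=0, keepdims=True)
    bn = b / np.linalg.norm(b, axis=0, keepdims=True)
    sim = an.T @ bn
    ri, ci = linear_sum_assignment(-sim)
    return float(sim[ri, ci].mean())


def select_n_signatures(
    matrix: pd.DataFrame | np.ndarray,
    k_range: range = range(2, 8),
    seed: int = 0,
    n_restarts: int = 5,
    stability_threshold: float = 0.85,
) -> int:
    """Choose K by reconstruction-error elbow gated on restart stability.

    For each K the decomposition is repeated across restarts; K is
    eligible only if the restart signatures agree (mean matched cosine
    >= threshold). Among eligible K the elbow of the best KL objective
    (largest drop in marginal improvement) is returned.
    """
    M = np.asarray(matrix, dtype=float)
    errs, stable = {}, {}
    for k in k_range:
        if k > M.shape[1]:
            break
        sigs = []
        best = np.inf
        for i in range(n_restarts):
            s, _ = extract_signatures(M, k, seed=seed * 1000 + k * 10 + i, n_restarts=1)
            sigs.append(s)
        s0, _ = extract_signatures(M, k, seed=seed, n_restarts=n_restarts)
        err = _kl_objective(M, s0)
        errs[k] = err
        stable[k] = float(np.mean([_match_cosine(sigs[0], s) for s in sigs[1:]])) if len(sigs) > 1 else 1.0
    eligible = [k for k in errs if stable[k] >= stability_threshold]
    if not eligible:
        eligible = list(errs)
    ks = sorted(errs)
    if len(ks) <= 2:
        return eligible[0]
    gains = {k: errs[ks[i - 1]] - errs[k] for i, k in enumerate(ks) if i > 0}
    best_k = eligible[0]
    best_drop = -np.inf
    for i, k in enumerate(ks[1:-1], start=1):
        if k not in eligible:
            continue
        drop = gains[k] - gains[ks[i + 1]]
        if drop > best_drop:
            best_drop, best_k = drop, k
    return best_k


def _kl_objective(M: np.ndarray, signatures: np.ndarray) -> float:
    E = project_exposures(M, signatures)
    R = np.clip(E @ signatures.T, 1e-12, None)
    Mc = np.clip(M, 1e-12, None)
    return float(np.sum(Mc * np.log(Mc / R) - Mc + R))


def project_exposures(counts: np.ndarray, signatures: np.ndarray) -> np.ndarray:
    """Non-negative least-squares exposures against frozen signatures."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    E = np.zeros((counts.shape[0], signatures.shape[1]))
    for i, row in enumerate(counts):
        E[i], _ = nnls(signatures, row)
    return E


# ---------------------------------------------------------------------------
# the CPS model


class ChromothripsisScoreModel:
    """Predictive model of chromothripsis presence from CN signatures.

    Parameters
    ----------
    profiles
        Filtered CN profiles (one per sample).
    labels
        Binary chromothripsis labels aligned with ``profiles`` (from a
        caller or ground truth).
    n_signatures
        Number of signatures K, or ``"auto"`` for elbow+stability
        selection.
    folds
        Stratified cross-validation folds for the reported AUC.
    seed
        Root seed; fixes categorization, NMF restarts and fold
        assignment, hence the entire model file.
    """

    def __init__(
        self,
        profiles: list[CNProfile],
        labels,
        *,
        n_signatures: int | str = 3,
        max_components: int = 8,
        folds: int = 10,
        n_restarts: int = 10,
        seed: int = 0,
    ):
        if len(profiles) != len(labels):
            raise ValueError("profiles and labels length mismatch")
        self.profiles = profiles
        self.labels = np.asarray(labels, dtype=int)
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present to fit the CPS model")
        self.n_signatures = n_signatures
        self.max_components = max_components
        self.folds = folds
        self.n_restarts = n_restarts
        self.seed = seed

    @classmethod
    def from_seg(cls, path, labels, genome=None, **kwargs) -> "ChromothripsisScoreModel":
        from .cn_profile import filter_profile, read_seg

        profiles = [filter_profile(p) for p in read_seg(path, genome=genome)]
        if isinstance(labels, dict):
            labels = [labels[p.sample_id] for p in profiles]
        return cls(profiles, labels, **kwargs)

    def fit(self) -> "CPSResults":
        vectors = [extract_cn_features(p) for p in self.profiles]
        counts, category_model = categorize_features(
            vectors, max_components=self.max_components, seed=self.seed
        )
        k = self.n_signatures
        if k == "auto":
            k = select_n_signatures(counts, seed=self.seed)
        signatures, _ = extract_signatures(
            counts, k, seed=self.seed, n_restarts=self.n_restarts
        )
        # exposures used by the GLM are NNLS projections against the frozen
        # signatures, so scoring a training sample reproduces its fitted value
        exposures = project_exposures(counts.values, signatures)

        glm_params, penalty, bse, pvalues = _fit_logistic(exposures, self.labels)
        cv_auc = self._cross_validate(exposures)
        return CPSResults(
            model=self,
            category_model=category_model,
            signatures=signatures,
            exposures=exposures,
            counts=counts,
            glm_params=glm_params,
            glm_bse=bse,
            glm_pvalues=pvalues,
            penalty=penalty,
            cv_auc=cv_auc,
            n_signatures=k,
            seed=self.seed,
            folds=self.folds,
        )

    def _cross_validate(self, exposures: np.ndarray) -> float:
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        oof = np.full(len(self.labels), np.nan)
        for train, test in skf.split(exposures, self.labels):
            params, _, _, _ = _fit_logistic(exposures[train], self.labels[train])
            oof[test] = expit(params[0] + exposures[test] @ params[1:])
        return float(roc_auc_score(self.labels, oof))


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Unpenalized logistic GLM; L2 fallback on separation/non-convergence.

    Returns (params [intercept, coefs...], penalty C or None, bse, pvalues).
    """
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            if res.converged and np.all(np.abs(params) < 30) and np.all(np.isfinite(res.bse)):
                return params, None, np.asarray(res.bse), np.asarray(res.pvalues)
        except Exception:
            pass
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)  # L2 by default
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return params, 1.0, None, None


@dataclass
class CPSResults:
    """Fitted CPS model: signatures, GLM coefficients, CV AUC."""

    model: ChromothripsisScoreModel | None
    category_model: CategoryModel
    signatures: np.ndarray
    exposures: np.ndarray
    counts: pd.DataFrame | None
    glm_params: np.ndarray
    glm_bse: np.ndarray | None
    glm_pvalues: np.ndarray | None
    penalty: float | None
    cv_auc: float
    n_signatures: int
    seed: int
    folds: int

    def predict(self, profiles: list[CNProfile]) -> pd.DataFrame:
        """Score profiles: features -> frozen categories -> NNLS exposures
        -> GLM probability (the CPS, in [0, 1])."""
        vectors = [extract_cn_features(p) for p in profiles]
        counts = self.category_model.transform(vectors)
        return self.predict_counts(counts)

    def predict_counts(self, counts: pd.DataFrame) -> pd.DataFrame:
        if list(counts.columns) != self.category_model.category_names:
            raise ValueError("category registry mismatch: counts were not produced "
                             "by this model's categorization")
        E = project_exposures(counts.values, self.signatures)
        cps = expit(self.glm_params[0] + E @ self.glm_params[1:])
        return pd.DataFrame({"sample": counts.index, "cps": cps}).set_index("sample")

    def summary(self) -> str:
        lines = [
            "Chromothripsis score (CPS) model",
            "=" * 40,
            f"samples:            {self.exposures.shape[0]}",
            f"categories:         {self.category_model.n_categories}",
            f"signatures (K):     {self.n_signatures}",
            f"{self.folds}-fold CV AUC:     {self.cv_auc:.3f}",
            f"penalty:            {'none' if self.penalty is None else f'L2 (C={self.penalty})'}",
            f"seed:               {self.seed}",
            "",
            f"{'term':<14}{'coef':>10}" + ("" if self.glm_bse is None else f"{'se':>10}{'p':>10}"),
        ]
        names = ["intercept"] + [f"signature_{i + 1}" for i in range(self.n_signatures)]
        for i, name in enumerate(names):
            row = f"{name:<14}{self.glm_params[i]:>10.4f}"
            if self.glm_bse is not None:
                row += f"{self.glm_bse[i]:>10.4f}{self.glm_pvalues[i]:>10.3g}"
            lines.append(row)
        return "\n".join(lines)

    def save(self, path) -> None:
        payload = {
            "category_model": self.category_model.to_dict(),
            "signatures": self.signatures.tolist(),
            "glm_params": self.glm_params.tolist(),
            "glm_bse": None if self.glm_bse is None else self.glm_bse.tolist(),
            "glm_pvalues": None if self.glm_pvalues is None else self.glm_pvalues.tolist(),
            "penalty": self.penalty,
            "cv_auc": self.cv_auc,
            "n_signatures": self.n_signatures,
            "seed": self.seed,
            "folds": self.folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def load(cls, path) -> "CPSResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=None,
            category_model=CategoryModel.from_dict(d["category_model"]),
            signatures=np.asarray(d["signatures"]),
            exposures=np.empty((0, d["n_signatures"])),
            counts=None,
            glm_params=np.asarray(d["glm_params"]),
            glm_bse=None if d["glm_bse"] is None else np.asarray(d["glm_bse"]),
            glm_pvalues=None if d["glm_pvalues"] is None else np.asarray(d["glm_pvalues"]),
            penalty=d["penalty"],
            cv_auc=d["cv_auc"],
            n_signatures=d["n_signatures"],
            seed=d["seed"],
            folds=d["folds"],
        )


def fit_cps_model(profiles, labels, folds: int = 10, seed: int = 0, **kwargs):
    """Functional facade: fit and return ``(results, cv_auc)``."""
    res = ChromothripsisScoreModel(profiles, labels, folds=folds, seed=seed, **kwargs).fit()
    return res, res.cv_auc


def score_cps(results: CPSResults, profile: CNProfile) -> float:
    """CPS of a single profile under a fitted model."""
    return float(results.predict([profile])["cps"].iloc[0])
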