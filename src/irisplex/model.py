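"""Multinomial-logistic eye-colour prediction.

The model is the standard baseline-category logit.  With effect-allele
dosages ``x_1..x_p`` and a reference category ``r``, each non-reference
category ``k`` has a linear predictor

    eta_k = alpha_k + sum_j beta_kj * x_j,        eta_r = 0,

and the category probabilities are the softmax ``p_k = exp(eta_k) /
sum_l exp(eta_l)``.  A categorical call is made only when the largest
probability reaches a threshold (0.7 by default); otherwise the profile is
*inconclusive*.

Two surfaces are provided: a statsmodels-style :class:`EyeColorModel` /
:class:`EyeColorResults` pair for fitting and prediction, and thin
functional wrappers (:func:`predict_probabilities`, :func:`call_eye_color`,
:func:`fit_parameters`) for one-off use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .panel import CATEGORIES, SnpPanel

__all__ = [
    "ParameterSet",
    "ProbabilityTriple",
    "EyeColorCall",
    "GenotypeRecord",
    "PhenotypeRecord",
    "EyeColorModel",
    "EyeColorResults",
    "predict_probabilities",
    "call_eye_color",
    "fit_parameters",
    "apply_missing_policy",
    "MissingGenotypeError",
    "PanelMismatchError",
    "ConvergenceError",
    "PerfectSeparationError",
]


class MissingGenotypeError(ValueError):
    """A required dosage is missing under the strict missing-data policy."""


class PanelMismatchError(ValueError):
    """Genotype and parameter set refer to different SNP panels."""


class ConvergenceError(RuntimeError):
    """The optimiser did not converge within the iteration budget."""


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded (separated data); refit with ridge > 0."""


@dataclass
class GenotypeRecord:
    """Per-sample effect-allele dosages, ordered by a :class:`SnpPanel`.

    Dosages are held as floats so that mean-imputed values (e.g. 0.238) can
    be represented; missing dosages are NaN.  Non-imputed records only ever
    contain 0, 1, 2 or NaN.
    """

    sample_id: str
    dosages: np.ndarray
    panel: SnpPanel
    imputed: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.panel),):
            raise ValueError(
                f"{self.sample_id}: expected {len(self.panel)} dosages, "
                f"got shape {self.dosages.shape}"
            )
        if not self.imputed:
            finite = self.dosages[~np.isnan(self.dosages)]
            if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
                raise ValueError(f"{self.sample_id}: dosages must be 0, 1, 2 or missing")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())


@dataclass(frozen=True)
class PhenotypeRecord:
    """An observed eye-colour label for one sample."""

    sample_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.sample_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class ProbabilityTriple:
    """Predicted probabilities for (blue, intermediate, brown); sums to 1."""

    p_blue: float
    p_intermediate: float
    p_brown: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("probabilities must be finite")
        if np.any(arr < -1e-12) or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must be in [0,1] and sum to 1, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_blue, self.p_intermediate, self.p_brown])

    def __getitem__(self, category: str) -> float:
        return self.as_array()[CATEGORIES.index(category)]


@dataclass(frozen=True)
class EyeColorCall:
    """A thresholded categorical call; ``inconclusive`` when no probability
    reaches the threshold (or the maximum is tied)."""

    call: str
    threshold: float
    winning_probability: float

    def __post_init__(self) -> None:
        if self.call not in CATEGORIES + ("inconclusive",):
            raise ValueError(f"invalid call {self.call!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Coefficients of the baseline-category logit model.

    ``alpha`` and ``beta`` are keyed by the two non-reference categories;
    each beta vector is ordered by ``panel``.  The reference category is
    explicit so parameter files are self-describing: probabilities are
    invariant to which category plays the reference role when coefficients
    are transformed consistently (see :meth:`with_reference`).
    """

    reference_category: str
    alpha: dict[str, float]
    beta: dict[str, np.ndarray]
    panel: SnpPanel
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.reference_category not in CATEGORIES:
            raise ValueError(f"unknown reference category {self.reference_category!r}")
        expected = set(CATEGORIES) - {self.reference_category}
        if set(self.alpha) != expected or set(self.beta) != expected:
            raise ValueError(
                f"alpha/beta must be keyed by the non-reference categories {sorted(expected)}"
            )
        beta = {k: np.asarray(v, dtype=float) for k, v in self.beta.items()}
        object.__setattr__(self, "beta", beta)
        for k, v in beta.items():
            if v.shape != (len(self.panel),):
                raise ValueError(f"beta[{k}] must have one effect per panel SNP")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"beta[{k}] contains non-finite values")
        if not all(np.isfinite(a) for a in self.alpha.values()):
            raise ValueError("alpha contains non-finite values")

    @property
    def nonreference_categories(self) -> tuple[str, ...]:
        return tuple(c for c in CATEGORIES if c != self.reference_category)

    def linear_predictors(self, dosages: np.ndarray) -> np.ndarray:
        """Linear predictors for all three categories, CATEGORIES order.

        ``dosages`` is (n, p) or (p,); returns (n, 3) or (3,).
        """
        X = np.atleast_2d(np.asarray(dosages, dtype=float))
        eta = np.zeros((X.shape[0], 3))
        for k in self.nonreference_categories:
            eta[:, CATEGORIES.index(k)] = self.alpha[k] + X @ self.beta[k]
        return eta[0] if np.asarray(dosages).ndim == 1 else eta

    def predict_proba(self, dosages: np.ndarray) -> np.ndarray:
        """Softmax probabilities in (blue, intermediate, brown) order.

        Numerically stable for arbitrarily large linear predictors via
        log-sum-exp normalisation.
        """
        eta = np.atleast_2d(self.linear_predictors(dosages))
        logp = eta - logsumexp(eta, axis=1, keepdims=True)
        p = np.exp(logp)
        return p[0] if np.asarray(dosages).ndim == 1 else p

    def with_reference(self, new_reference: str) -> "ParameterSet":
        """Re-express the same model with a different reference category."""
        if new_reference == self.reference_category:
            return self
        if new_reference not in CATEGORIES:
            raise ValueError(f"unknown category {new_reference!r}")
        # subtract the new reference's linear predictor from every category
        a_new = self.alpha.get(new_reference, 0.0)
        b_new = self.beta.get(
            new_reference, np.zeros(len(self.panel))
        )
        alpha, beta = {}, {}
        for k in CATEGORIES:
            if k == new_reference:
                continue
            a_k = self.alpha.get(k, 0.0)
            b_k = self.beta.get(k, np.zeros(len(self.panel)))
            alpha[k] = a_k - a_new
            beta[k] = b_k - b_new
        return ParameterSet(
            reference_category=new_reference,
            alpha=alpha,
            beta=beta,
            panel=self.panel,
            provenance=self.provenance,
        )


def predict_probabilities(g: GenotypeRecord, params: ParameterSet) -> ProbabilityTriple:
    """Category probabilities for one genotype record.

    The record must be complete (apply a missing-data policy first).
    """
    if g.panel.rs_ids != params.panel.rs_ids:
        raise PanelMismatchError(
            f"{g.sample_id}: record panel {g.panel.rs_ids} != parameter panel {params.panel.rs_ids}"
        )
    if g.has_missing:
        missing = [rs for rs, m in zip(g.panel.rs_ids, g.missing_mask) if m]
        raise MissingGenotypeError(
            f"{g.sample_id}: missing dosage for {', '.join(missing)} under strict policy"
        )
    p = params.predict_proba(g.dosages)
    return ProbabilityTriple(*p)


def call_eye_color(p: ProbabilityTriple, threshold: float = 0.7) -> EyeColorCall:
    """Call the arg-max category when its probability reaches the threshold
    (inclusive); otherwise, or on an exact arg-max tie, return inconclusive."""
    if not 1.0 / 3.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (1/3, 1], got {threshold}")
    arr = p.as_array()
    top = arr.max()
    if top < threshold or (arr == top).sum() > 1:
        return EyeColorCall("inconclusive", threshold, float(top))
    return EyeColorCall(CATEGORIES[int(arr.argmax())], threshold, float(top))


def apply_missing_policy(
    g: GenotypeRecord,
    policy: str,
    frequencies: dict[str, float] | None = None,
) -> GenotypeRecord:
    """Resolve missing dosages before prediction.

    strict
        Any missing dosage raises :class:`MissingGenotypeError`.
    mean-impute
        Missing dosages are replaced by 2 x effect-allele frequency
        (the Hardy-Weinberg expectation) and the record is flagged imputed.
    """
    if policy not in ("strict", "mean-impute"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if not g.has_missing:
        return g
    if policy == "strict":
        missing = [rs for rs, m in zip(g.panel.rs_ids, g.missing_mask) if m]
        raise MissingGenotypeError(
            f"{g.sample_id}: missing dosage for {', '.join(missing)} under strict policy"
        )
    if frequencies is None:
        raise ValueError("mean-impute requires effect-allele frequencies")
    dosages = g.dosages.copy()
    for j, rs in enumerate(g.panel.rs_ids):
        if np.isnan(dosages[j]):
            if rs not in frequencies:
                raise ValueError(f"no effect-allele frequency supplied for {rs}")
            dosages[j] = 2.0 * frequencies[rs]
    return GenotypeRecord(g.sample_id, dosages, g.panel, imputed=True)


# ---------------------------------------------------------------------------
# Fitting


def _design(genotypes: Sequence[GenotypeRecord]) -> np.ndarray:
    X = np.vstack([g.dosages for g in genotypes])
    if np.isnan(X).any():
        raise MissingGenotypeError("fitting requires complete dosages")
    return X


class EyeColorModel:
    """Multinomial-logistic model of eye colour on effect-allele dosages.

    Parameters
    ----------
    dosages : (n, p) array of effect-allele dosages, panel order
    categories : length-n sequence of labels from {blue, intermediate, brown}
    panel : the SNP panel defining the dosage columns
    reference : baseline category whose linear predictor is fixed at zero
    """

    def __init__(self, dosages, categories, panel: SnpPanel, reference: str = "blue"):
        self.X = np.asarray(dosages, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(panel):
            raise ValueError("dosage matrix must be (n, |panel|)")
        if np.isnan(self.X).any():
            raise MissingGenotypeError("fitting requires complete dosages")
        cats = list(categories)
        if len(cats) != self.X.shape[0]:
            raise ValueError("categories and dosage rows must align")
        unknown = set(cats) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if set(cats) != set(CATEGORIES):
            raise ValueError("need at least one sample in each of the three categories")
        if reference not in CATEGORIES:
            raise ValueError(f"unknown reference category {reference!r}")
        self.panel = panel
        self.reference = reference
        self.nonref = tuple(c for c in CATEGORIES if c != reference)
        # one-hot truth for the two non-reference categories
        self.Y = np.stack([[c == k for c in cats] for k in self.nonref], axis=1).astype(float)
        self.n, self.p = self.X.shape
        self.df_model = 2 * (self.p + 1)
        self.Z = np.hstack([np.ones((self.n, 1)), self.X])  # intercept-augmented design

    @classmethod
    def from_records(
        cls,
        genotypes: Sequence[GenotypeRecord],
        phenotypes: Sequence[PhenotypeRecord],
        reference: str = "blue",
    ) -> "EyeColorModel":
        if not genotypes:
            raise ValueError("no genotype records")
        by_id = {ph.sample_id: ph.category for ph in phenotypes}
        missing = [g.sample_id for g in genotypes if g.sample_id not in by_id]
        if missing:
            raise ValueError(f"no phenotype for samples: {missing[:5]}")
        panel = genotypes[0].panel
        X = _design(genotypes)
        cats = [by_id[g.sample_id] for g in genotypes]
        return cls(X, cats, panel, reference=reference)

    @classmethod
    def from_dataframe(cls, df, panel: SnpPanel, phenotype_col: str = "eye_color",
                       reference: str = "blue") -> "EyeColorModel":
        """Build from a tidy frame with one dosage column per rs id."""
        missing = [rs for rs in panel.rs_ids if rs not in df.columns]
        if missing:
            raise ValueError(f"dataframe lacks dosage columns: {missing}")
        X = df[list(panel.rs_ids)].to_numpy(dtype=float)
        return cls(X, df[phenotype_col].tolist(), panel, reference=reference)

    # -- likelihood machinery ------------------------------------------------

    def _unpack(self, w: np.ndarray) -> np.ndarray:
        return w.reshape(2, self.p + 1)

    def _eta(self, W: np.ndarray) -> np.ndarray:
        """(n, 3) linear predictors in CATEGORIES order; reference column 0."""
        eta = np.zeros((self.n, 3))
        for i, k in enumerate(self.nonref):
            eta[:, CATEGORIES.index(k)] = self.Z @ W[i]
        return eta

    def loglike(self, w: np.ndarray) -> float:
        W = self._unpack(w)
        eta_nr = self.Z @ W.T  # (n, 2)
        lse = logsumexp(np.hstack([np.zeros((self.n, 1)), eta_nr]), axis=1)
        return float((self.Y * eta_nr).sum() - lse.sum())

    def _probs_nonref(self, w: np.ndarray) -> np.ndarray:
        W = self._unpack(w)
        eta_nr = self.Z @ W.T
        lse = logsumexp(np.hstack([np.zeros((self.n, 1)), eta_nr]), axis=1, keepdims=True)
        return np.exp(eta_nr - lse)  # (n, 2)

    def score(self, w: np.ndarray) -> np.ndarray:
        P = self._probs_nonref(w)
        return ((self.Y - P).T @ self.Z).ravel()

    def hessian(self, w: np.ndarray) -> np.ndarray:
        """Hessian of the log-likelihood (negative definite away from separation)."""
        P = self._probs_nonref(w)
        q = self.p + 1
        H = np.zeros((2 * q, 2 * q))
        for a in range(2):
            for b in range(2):
                wgt = P[:, a] * ((a == b) - P[:, b])
                H[a * q:(a + 1) * q, b * q:(b + 1) * q] = -(self.Z * wgt[:, None]).T @ self.Z
        return H

    def fit(
        self,
        maxiter: int = 200,
        gtol: float = 1e-8,
        ftol: float = 1e-10,
        ridge: float = 0.0,
    ) -> "EyeColorResults":
        """Maximise the log-likelihood by Newton-Raphson with step halving.

        Deterministic: initialisation at zero, no randomness.  ``ridge`` adds
        a quadratic penalty ``-ridge/2 * ||w||^2`` to stabilise separated
        data; the result is flagged as ridge-stabilised in its provenance.
        """
        q = self.p + 1
        w = np.zeros(2 * q)
        ll = self.loglike(w) - 0.5 * ridge * w @ w
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            g = self.score(w) - ridge * w
            H = self.hessian(w) - ridge * np.eye(2 * q)
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                raise PerfectSeparationError(
                    "singular Hessian: data are separated; refit with ridge > 0"
                )
            # backtracking line search on the (penalised) log-likelihood
            t = 1.0
            for _ in range(60):
                w_new = w + t * step
                ll_new = self.loglike(w_new) - 0.5 * ridge * w_new @ w_new
                if ll_new > ll - 1e-14:
                    break
                t *= 0.5
            improvement = ll_new - ll
            w, ll = w_new, ll_new
            if ridge == 0.0 and np.max(np.abs(w)) > 50.0:
                raise PerfectSeparationError(
                    f"coefficients diverging (max |w| > 50 at iteration {it}): "
                    "data are separated; refit with ridge > 0"
                )
            if improvement < ftol and np.max(np.abs(self.score(w) - ridge * w)) < 1e-4:
                converged = True
                break
        if not converged:
            g = self.score(w) - ridge * w
            raise ConvergenceError(
                f"no convergence after {maxiter} iterations "
                f"(loglike={ll:.6f}, max|grad|={np.max(np.abs(g)):.3e})"
            )
        return EyeColorResults(self, w, llf=self.loglike(w), niter=it, ridge=ridge)


class EyeColorResults:
    """Fitted multinomial-logistic model: estimates, uncertainties, prediction."""

    def __init__(self, model: EyeColorModel, w: np.ndarray, llf: float, niter: int,
                 ridge: float = 0.0):
        self.model = model
        self._w = np.asarray(w, dtype=float)
        self.llf = llf
        self.niter = niter
        self.ridge = ridge
        self.converged = True

    @property
    def parameter_set(self) -> ParameterSet:
        W = self.model._unpack(self._w)
        prov = "fitted by irisplex (Newton-Raphson MLE)"
        if self.ridge > 0:
            prov += f"; ridge-stabilised (ridge={self.ridge:g})"
        return ParameterSet(
            reference_category=self.model.reference,
            alpha={k: float(W[i, 0]) for i, k in enumerate(self.model.nonref)},
            beta={k: W[i, 1:].copy() for i, k in enumerate(self.model.nonref)},
            panel=self.model.panel,
            provenance=prov,
        )

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the inverse observed information, shaped like
        the flat coefficient vector (2 x (1+p))."""
        H = self.model.hessian(self._w)
        if self.ridge > 0:
            H = H - self.ridge * np.eye(H.shape[0])
        cov = np.linalg.inv(-H)
        return np.sqrt(np.diag(cov))

    @property
    def params(self):
        """Tidy coefficient table with standard errors."""
        import pandas as pd

        q = self.model.p + 1
        names = ["intercept", *self.model.panel.rs_ids]
        rows = []
        bse = self.bse
        for i, k in enumerate(self.model.nonref):
            for j, nm in enumerate(names):
                rows.append(
                    {
                        "category": k,
                        "term": nm,
                        "estimate": self._w[i * q + j],
                        "std_err": bse[i * q + j],
                    }
                )
        return pd.DataFrame(rows)

    def predict_proba(self, dosages: np.ndarray) -> np.ndarray:
        return self.parameter_set.predict_proba(dosages)

    def predict(self, genotypes: Sequence[GenotypeRecord], threshold: float = 0.7):
        """Per-record (ProbabilityTriple, EyeColorCall) pairs."""
        ps = self.parameter_set
        out = []
        for g in genotypes:
            trip = predict_probabilities(g, ps)
            out.append((trip, call_eye_color(trip, threshold)))
        return out

    def summary(self) -> str:
        lines = [
            "Multinomial logistic eye-colour model",
            f"  n = {self.model.n}, SNPs = {self.model.p}, "
            f"reference = {self.model.reference}",
            f"  log-likelihood = {self.llf:.4f}  (Newton iterations: {self.niter})",
        ]
        if self.ridge > 0:
            lines.append(f"  ridge penalty: {self.ridge:g}")
        tbl = self.params
        lines.append(f"{'category':>14} {'term':>12} {'estimate':>12} {'std err':>10}")
        for _, r in tbl.iterrows():
            lines.append(
                f"{r['category']:>14} {r['term']:>12} {r['estimate']:>12.4f} {r['std_err']:>10.4f}"
            )
        return "\n".join(lines)


def fit_parameters(
    genotypes: Sequence[GenotypeRecord],
    phenotypes: Sequence[PhenotypeRecord],
    reference_category: str = "blue",
    **fit_kwargs,
) -> ParameterSet:
    """Maximum-likelihood parameter estimation; see :class:`EyeColorModel`."""
    model = EyeColorModel.from_records(genotypes, phenotypes, reference=reference_category)
    return model.fit(**fit_kwargs).parameter_set
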