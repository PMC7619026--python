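"""Multiplexed fingerprint analysis: Fisher linear discriminant classification.

A *fingerprint* is the vector of step-shift responses (delta-RIU) of one
analyte exposure across the recognition channels of the array (backbone
control P2 and glycopolymers P3-A..E).  Lectins are discriminated by Fisher
LDA: the between-class scatter ``Sb`` is maximised relative to the pooled
within-class scatter ``Sw`` by solving the generalized eigenproblem
``Sb v = l Sw v``; the leading eigenvectors are the canonical factors
(F1, F2, ...).  Classification is nearest class centroid in the canonical
space, which — because the axes are Sw-orthonormal — is the Gaussian
equal-covariance rule restricted to the discriminant subspace.  Confidence is
the max posterior under that Gaussian model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "FingerprintMatrix",
    "LinearDiscriminantModel",
    "LDAResults",
    "fit_lda",
    "loocv",
    "holdout_validate",
    "build_fingerprints",
    "ClassificationError",
]


class ClassificationError(ValueError):
    pass


@dataclass
class FingerprintMatrix:
    """Samples x recognition-channel delta-RIU table with class labels."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise ClassificationError("X and y must have the same number of rows")
        if self.X.isna().to_numpy().any():
            raise ClassificationError("fingerprints contain missing values after QC")

    @property
    def channels(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "FingerprintMatrix":
        return FingerprintMatrix(X=self.X.iloc[idx], y=self.y[idx])

    def to_csv(self, path) -> None:
        df = self.X.copy()
        df.insert(0, "class", self.y)
        df.to_csv(path, index_label="sample_id")

    @classmethod
    def read_csv(cls, path) -> "FingerprintMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        if "class" not in df.columns:
            raise ClassificationError("fingerprint CSV needs a 'class' column")
        y = df.pop("class").to_numpy(dtype=object)
        return cls(X=df.astype(float), y=y)


class LinearDiscriminantModel:
    """Fisher LDA model for a fingerprint matrix.

    Parameters
    ----------
    fm
        Training fingerprints; needs >= 2 classes and >= 2 samples per class.
    priors
        ``"equal"`` (default; replicates are balanced by design) or
        ``"proportional"``.
    """

    def __init__(self, fm: FingerprintMatrix, *, priors: str = "equal", min_class_size: int = 2):
        if priors not in ("equal", "proportional"):
            raise ClassificationError("priors must be 'equal' or 'proportional'")
        if len(fm.classes) < 2:
            raise ClassificationError("discrimination needs >= 2 classes")
        counts = pd.Series(fm.y).value_counts()
        if (counts < min_class_size).any():
            bad = counts[counts < min_class_size].index.tolist()
            raise ClassificationError(f"classes with < {min_class_size} samples: {bad}")
        if fm.n_samples <= len(fm.classes):
            raise ClassificationError("within-class scatter needs n > number of classes")
        self.fm = fm
        self.priors = priors

    def fit(self, *, shrinkage: float = 1e-6, cond_threshold: float = 1e8) -> "LDAResults":
        """Solve the between/within generalized eigenproblem.

        ``Sw`` gets a diagonal ridge ``shrinkage * trace(Sw)/p`` when its
        condition number exceeds ``cond_threshold``; a scatter that stays
        numerically singular after regularisation is an error.
        """
        X = self.fm.X.to_numpy(dtype=float)
        y = self.fm.y
        classes = self.fm.classes
        n, p = X.shape
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        counts = np.array([(y == c).sum() for c in classes])
        if self.priors == "equal":
            prior = np.full(len(classes), 1.0 / len(classes))
        else:
            prior = counts / n
        grand = (prior[:, None] * means).sum(axis=0)
        Sw = np.zeros((p, p))
        for c, mu in zip(classes, means):
            d = X[y == c] - mu
            Sw += d.T @ d
        Sw /= n - len(classes)
        dm = means - grand
        Sb = (prior[:, None] * dm).T @ dm
        cond = np.linalg.cond(Sw)
        if not np.isfinite(cond) or cond > cond_threshold:
            Sw = Sw + shrinkage * (np.trace(Sw) / p) * np.eye(p)
            cond = np.linalg.cond(Sw)
            if not np.isfinite(cond) or cond > 1e14:
                raise ClassificationError(
                    f"within-class scatter singular after regularisation (cond={cond:.3g})"
                )
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1]
        k = min(len(classes) - 1, p)
        evals = np.clip(evals[order][:k], 0.0, None)
        axes = evecs[:, order][:, :k]
        # deterministic sign: largest-magnitude loading positive
        for j in range(k):
            i = np.argmax(np.abs(axes[:, j]))
            if axes[i, j] < 0:
                axes[:, j] = -axes[:, j]
        return LDAResults(
            model=self,
            classes=classes,
            channels=self.fm.channels,
            class_means=means,
            grand_mean=grand,
            priors=prior,
            Sw=Sw,
            Sb=Sb,
            eigenvalues=evals,
            axes=axes,
        )


@dataclass
class LDAResults:
    """Fitted discriminant axes plus classification and diagnostics."""

    model: LinearDiscriminantModel
    classes: np.ndarray
    channels: list[str]
    class_means: np.ndarray
    grand_mean: np.ndarray
    priors: np.ndarray
    Sw: np.ndarray
    Sb: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray
    scores: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.scores = self.transform(self.model.fm.X)

    @property
    def n_factors(self) -> int:
        return self.axes.shape[1]

    @property
    def explained_ratio(self) -> np.ndarray:
        """Fraction of between-class variance carried by each canonical factor."""
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def transform(self, X) -> pd.DataFrame:
        idx = X.index if isinstance(X, pd.DataFrame) else None
        Xa = np.asarray(X, dtype=float)
        sc = (Xa - self.grand_mean) @ self.axes
        return pd.DataFrame(sc, index=idx, columns=[f"F{j + 1}" for j in range(self.n_factors)])

    def _distances(self, X) -> np.ndarray:
        sc = self.transform(X).to_numpy()
        centroids = (self.class_means - self.grand_mean) @ self.axes
        return np.linalg.norm(sc[:, None, :] - centroids[None, :, :], axis=-1)

    def predict(self, X) -> np.ndarray:
        d = self._distances(X)
        logp = -0.5 * d**2 + np.log(self.priors)[None, :]
        return self.classes[np.argmax(logp, axis=1)]

    def posterior(self, X) -> pd.DataFrame:
        """Gaussian equal-covariance class posteriors (model-based confidence)."""
        d = self._distances(X)
        logp = -0.5 * d**2 + np.log(self.priors)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        idx = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(p, index=idx, columns=list(self.classes))

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.fm.X) == self.model.fm.y))

    def confidence_ellipse(self, cls, level: float = 0.95) -> dict:
        """95% (by default) ellipse of a class's scores in the (F1, F2) plane.

        Chi-square quantile with 2 df applied to the per-class score
        covariance; returns centre, semi-axes and orientation (radians).
        """
        from scipy.stats import chi2

        if self.n_factors < 2:
            raise ClassificationError("need >= 2 canonical factors for an ellipse")
        mask = self.model.fm.y == cls
        sc = self.scores.to_numpy()[mask][:, :2]
        centre = sc.mean(axis=0)
        cov = np.cov(sc, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        r = np.sqrt(chi2.ppf(level, df=2))
        return {
            "centre": centre,
            "semi_axes": r * np.sqrt(np.clip(evals[::-1], 0, None)),
            "angle_rad": float(np.arctan2(evecs[1, -1], evecs[0, -1])),
        }

    def plot_scores(self, ax=None, *, level: float = 0.95):
        """Canonical score plot (F1 vs F2) with per-class confidence ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for cls in self.classes:
            mask = self.model.fm.y == cls
            sc = self.scores.to_numpy()[mask]
            pts = ax.scatter(sc[:, 0], sc[:, 1] if self.n_factors > 1 else np.zeros(mask.sum()), label=str(cls), s=18)
            if self.n_factors > 1 and mask.sum() > 2:
                e = self.confidence_ellipse(cls, level)
                ax.add_patch(
                    Ellipse(
                        e["centre"],
                        2 * e["semi_axes"][0],
                        2 * e["semi_axes"][1],
                        angle=np.degrees(e["angle_rad"]),
                        fill=False,
                        ls="--",
                        color=pts.get_facecolor()[0],
                    )
                )
        ex = self.explained_ratio
        ax.set_xlabel(f"F1 ({100 * ex[0]:.1f}% of between-class variance)")
        if self.n_factors > 1:
            ax.set_ylabel(f"F2 ({100 * ex[1]:.1f}%)")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        lines = ["Linear discriminant analysis", "=" * 30]
        lines.append(f"classes: {', '.join(map(str, self.classes))}")
        lines.append(f"channels: {', '.join(self.channels)}")
        lines.append(f"n = {self.model.fm.n_samples}, canonical factors = {self.n_factors}")
        for j, (ev, ex) in enumerate(zip(self.eigenvalues, self.explained_ratio)):
            lines.append(f"  F{j + 1}: eigenvalue {ev:10.4g}  ({100 * ex:5.1f}% between-class variance)")
        lines.append(f"training accuracy: {100 * self.training_accuracy():.1f}%")
        return "\n".join(lines)


def fit_lda(fm: FingerprintMatrix, *, priors: str = "equal", **fit_kw) -> LDAResults:
    """Fit Fisher LDA to a fingerprint matrix (convenience wrapper)."""
    return LinearDiscriminantModel(fm, priors=priors).fit(**fit_kw)


def loocv(fm: FingerprintMatrix, *, priors: str = "equal", **fit_kw) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validation: refit without each sample, reclassify it.

    Returns (accuracy, confusion matrix with true classes as rows).
    """
    counts = pd.Series(fm.y).value_counts()
    if (counts < 2).any():
        raise ClassificationError("LOOCV needs >= 2 samples per class")
    classes = fm.classes
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    correct = 0
    n = fm.n_samples
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        # the left-out sample's class may drop to a single member; its
        # scatter contribution is then zero, which the refit tolerates
        res = LinearDiscriminantModel(
            fm.subset(np.where(keep)[0]), priors=priors, min_class_size=1
        ).fit(**fit_kw)
        pred = res.predict(fm.X.iloc[[i]])[0]
        confusion.loc[fm.y[i], pred] += 1
        correct += pred == fm.y[i]
    return correct / n, confusion


def holdout_validate(
    train_fm: FingerprintMatrix,
    test_fm: FingerprintMatrix,
    *,
    priors: str = "equal",
    **fit_kw,
) -> tuple[float, pd.DataFrame]:
    """Fit on the training set, classify held-out samples.

    Returns (accuracy, per-sample table with prediction and max-posterior
    confidence).
    """
    if train_fm.channels != test_fm.channels:
        raise ClassificationError(
            f"channel mismatch: train {train_fm.channels} vs test {test_fm.channels}"
        )
    if test_fm.n_samples == 0:
        raise ClassificationError("empty test set")
    res = LinearDiscriminantModel(train_fm, priors=priors).fit(**fit_kw)
    pred = res.predict(test_fm.X)
    post = res.posterior(test_fm.X)
    table = pd.DataFrame(
        {
            "true": test_fm.y,
            "predicted": pred,
            "confidence": post.to_numpy().max(axis=1),
        },
        index=test_fm.X.index,
    )
    acc = float(np.mean(pred == test_fm.y))
    return acc, table


def build_fingerprints(
    records,
    *,
    t_pre: float,
    t_post: float,
    window: int = 20,
    channels: list[str] | None = None,
) -> FingerprintMatrix:
    """Assemble a fingerprint matrix from per-sensor traces.

    ``records`` is an iterable of ``(analyte, replicate, channel, trace)``
    where ``trace`` is a :class:`~cgmr.track.SensorTrace`; the entry is the
    20-point step shift (mean after minus mean before the binding step, see
    :func:`cgmr.kinetics.extract_step`).  Records with ``channel=None`` are
    excluded; a (analyte, replicate) row missing any channel is dropped with
    a warning.
    """
    from .kinetics import extract_step

    rows: dict[tuple[str, str], dict[str, float]] = {}
    chan_seen: list[str] = list(channels) if channels else []
    for analyte, replicate, channel, trace in records:
        if channel is None:
            warnings.warn(f"sensor of ({analyte}, {replicate}) unmapped; excluded", stacklevel=2)
            continue
        if channel not in chan_seen:
            if channels is not None:
                warnings.warn(f"unknown channel {channel!r}; excluded", stacklevel=2)
                continue
            chan_seen.append(channel)
        rows.setdefault((str(analyte), str(replicate)), {})[channel] = extract_step(
            trace, t_pre=t_pre, t_post=t_post, window=window
        )
    data, labels, ids = [], [], []
    for (analyte, replicate), vals in rows.items():
        missing = [c for c in chan_seen if c not in vals]
        if missing:
            warnings.warn(
                f"sample ({analyte}, {replicate}) missing channels {missing}; row dropped",
                stacklevel=2,
            )
            continue
        data.append([vals[c] for c in chan_seen])
        labels.append(analyte)
        ids.append(f"{analyte}-{replicate}")
    if not data:
        raise ClassificationError("no complete fingerprint rows")
    X = pd.DataFrame(np.asarray(data, dtype=float), index=ids, columns=chan_seen)
    return FingerprintMatrix(X=X, y=np.asarray(labels, dtype=object))
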