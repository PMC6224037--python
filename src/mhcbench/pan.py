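"""Pan-allele neural-network affinity predictor.

A single model covers every allele with a known 34-residue binding-pocket
pseudo-sequence: the input is the one-hot encoding of the 9-mer peptide
concatenated with the one-hot pseudo-sequence (43 positions x 20 residues =
860 features), and the output is the normalised log-affinity
``y = 1 - log10(IC50)/log10(50000)`` squashed through a sigmoid.  Alleles
with similar binding pockets share input features, so the network can
generalise to alleles absent from training — the leave-one-allele-out
protocol (:func:`leave_one_allele_out`) measures exactly that.

The network itself is deliberately small — one hidden layer (default 64
tanh units, dropout 0.1 during training), mean-squared-error loss, Adam —
and is implemented directly on numpy so that training is single-threaded,
dependency-light and bit-reproducible for a fixed seed.

The public surface follows the model/results convention of statistical
modelling packages::

    model = PanAlleleANN.from_dataframe(df, pseudo_table)
    res = model.fit()
    res.predict(peptides, alleles)   # scores in [0,1] and nM values
    print(res.summary())
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    AffinityMeasurement,
    DomainError,
    inverse_transform,
    transform_affinity,
)

__all__ = [
    "PSEUDO_LENGTH",
    "AllelePseudoSequence",
    "PanModelConfig",
    "PanAlleleANN",
    "PanAlleleResults",
    "encode_pair",
    "leave_one_allele_out",
]

PSEUDO_LENGTH = 34
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class AllelePseudoSequence:
    """Canonical allele id plus its 34-mer binding-pocket pseudo-sequence."""

    allele: str
    pseudo: str

    def __post_init__(self) -> None:
        if len(self.pseudo) != PSEUDO_LENGTH:
            raise DomainError(
                f"pseudo-sequence for {self.allele} has length {len(self.pseudo)}, "
                f"expected {PSEUDO_LENGTH}"
            )
        bad = set(self.pseudo) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise DomainError(f"invalid residues {sorted(bad)} in pseudo-sequence")


@dataclass(frozen=True)
class PanModelConfig:
    """Architecture and training hyperparameters with pinned defaults."""

    hidden_units: int = 64
    dropout: float = 0.1
    peptide_length: int = 9
    activation: str = "tanh"
    epochs: int = 250
    batch_size: int = 128
    learning_rate: float = 1e-3
    unknown_residue: str = "zero"  # or "uniform" (0.05 smoothing)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise DomainError("dropout must lie in [0, 1)")
        if self.hidden_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise DomainError("hidden_units, epochs and batch_size must be positive")
        if self.activation != "tanh":
            raise DomainError("only tanh hidden activation is supported")
        if self.unknown_residue not in ("zero", "uniform"):
            raise DomainError("unknown_residue must be 'zero' or 'uniform'")

    @property
    def input_positions(self) -> int:
        return self.peptide_length + PSEUDO_LENGTH

    @property
    def n_features(self) -> int:
        return self.input_positions * 20


def _encode_sequences(seqs: Sequence[str], length: int, unknown: str) -> np.ndarray:
    """One-hot encode equal-length sequences to (n, length*20)."""
    n = len(seqs)
    out = np.zeros((n, length, 20), dtype=np.float32)
    fill = 0.05 if unknown == "uniform" else None
    for i, seq in enumerate(seqs):
        if len(seq) != length:
            raise DomainError(f"sequence {seq!r} has length {len(seq)}, expected {length}")
        for j, aa in enumerate(seq):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                out[i, j, idx] = 1.0
            elif aa == "X":
                if fill is not None:
                    out[i, j, :] = fill
            else:
                raise DomainError(f"invalid residue {aa!r} in sequence {seq!r}")
    return out.reshape(n, length * 20)


def encode_pair(
    peptide: str,
    pseudo: AllelePseudoSequence | str,
    config: PanModelConfig = PanModelConfig(),
) -> np.ndarray:
    """Encode one (peptide, pseudo-sequence) pair to the 860-length input.

    Peptide positions 1-9 come first, then pseudo positions 1-34; each
    position is a 20-long one-hot block.  An 'X' residue yields an all-zero
    block by default, or uniform 0.05 under the smoothing option.
    """
    pseq = pseudo.pseudo if isinstance(pseudo, AllelePseudoSequence) else pseudo
    if len(pseq) != PSEUDO_LENGTH:
        raise DomainError(f"pseudo-sequence has length {len(pseq)}, expected {PSEUDO_LENGTH}")
    pep = _encode_sequences([peptide], config.peptide_length, config.unknown_residue)
    ps = _encode_sequences([pseq], PSEUDO_LENGTH, config.unknown_residue)
    return np.concatenate([pep[0], ps[0]])


def _encode_dataset(
    peptides: Sequence[str],
    pseudos: Sequence[str],
    config: PanModelConfig,
) -> np.ndarray:
    pep = _encode_sequences(list(peptides), config.peptide_length, config.unknown_residue)
    ps = _encode_sequences(list(pseudos), PSEUDO_LENGTH, config.unknown_residue)
    return np.hstack([pep, ps])


def _pseudo_table_hash(table: Mapping[str, str]) -> str:
    digest = hashlib.sha256()
    for allele in sorted(table):
        digest.update(f"{allele}\t{table[allele]}\n".encode())
    return digest.hexdigest()[:16]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PanAlleleANN:
    """Pan-allele affinity regression model (unfitted).

    Parameters
    ----------
    measurements
        Training records; targets are the normalised log-affinities of their
        nM values.
    pseudo_table
        Mapping allele id -> 34-mer pseudo-sequence.  Every training allele
        must be present; prediction covers any allele in the table.
    config
        Architecture / optimisation settings, see :class:`PanModelConfig`.
    """

    def __init__(
        self,
        measurements: Sequence[AffinityMeasurement],
        pseudo_table: Mapping[str, str],
        config: PanModelConfig = PanModelConfig(),
    ) -> None:
        if not measurements:
            raise DomainError("no training measurements supplied")
        missing = sorted({m.allele for m in measurements} - set(pseudo_table))
        if missing:
            raise DomainError(
                f"alleles lack a pseudo-sequence: {missing}; provide them in "
                "pseudo_table before training"
            )
        self.config = config
        self.pseudo_table = {a: p for a, p in pseudo_table.items()}
        self.measurements = list(measurements)
        self.training_alleles = frozenset(m.allele for m in measurements)
        self.exog = _encode_dataset(
            [m.peptide for m in self.measurements],
            [self.pseudo_table[m.allele] for m in self.measurements],
            config,
        )
        self.endog = np.asarray(
            transform_affinity([m.value_nm for m in self.measurements]),
            dtype=np.float32,
        ).reshape(-1, 1)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        pseudo_table: Mapping[str, str],
        config: PanModelConfig = PanModelConfig(),
        *,
        peptide_col: str = "peptide",
        allele_col: str = "allele",
        value_col: str = "value_nm",
    ) -> "PanAlleleANN":
        """Build the model from a tidy measurement table."""
        from .core import AssayType

        measurements = [
            AffinityMeasurement(
                str(row[peptide_col]), str(row[allele_col]), AssayType.IC50,
                float(row[value_col]),
            )
            for _, row in data.iterrows()
        ]
        return cls(measurements, pseudo_table, config)

    def fit(self, *, verbose: bool = False) -> "PanAlleleResults":
        """Train with minibatch Adam on MSE; deterministic for the config seed.

        Dropout (inverted scaling) is applied to the hidden layer only during
        training.  Returns a :class:`PanAlleleResults` carrying the weights
        and the per-epoch loss trace.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, d = self.exog.shape
        h = cfg.hidden_units
        # Glorot-uniform init
        lim1 = np.sqrt(6.0 / (d + h))
        lim2 = np.sqrt(6.0 / (h + 1))
        params = {
            "W1": rng.uniform(-lim1, lim1, size=(d, h)).astype(np.float64),
            "b1": np.zeros(h),
            "W2": rng.uniform(-lim2, lim2, size=(h, 1)).astype(np.float64),
            "b2": np.zeros(1),
        }
        m_t = {k: np.zeros_like(v) for k, v in params.items()}
        v_t = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        keep = 1.0 - cfg.dropout

        X = self.exog.astype(np.float64)
        Y = self.endog.astype(np.float64)
        loss_trace: list[float] = []
        step = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], Y[idx]
                z1 = xb @ params["W1"] + params["b1"]
                a1 = np.tanh(z1)
                if cfg.dropout > 0:
                    mask = (rng.random(a1.shape) < keep) / keep
                    a1 = a1 * mask
                z2 = a1 @ params["W2"] + params["b2"]
                out = _sigmoid(z2)
                err = out - yb
                epoch_loss += float((err**2).sum())
                # backprop through MSE -> sigmoid -> linear -> dropout -> tanh
                b = len(idx)
                d_z2 = (2.0 / b) * err * out * (1.0 - out)
                grads = {
                    "W2": a1.T @ d_z2,
                    "b2": d_z2.sum(axis=0),
                }
                d_a1 = d_z2 @ params["W2"].T
                if cfg.dropout > 0:
                    d_a1 = d_a1 * mask
                d_z1 = d_a1 * (1.0 - np.tanh(z1) ** 2)
                grads["W1"] = xb.T @ d_z1
                grads["b1"] = d_z1.sum(axis=0)
                step += 1
                for k in params:
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * grads[k]
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m_t[k] / (1 - beta1**step)
                    v_hat = v_t[k] / (1 - beta2**step)
                    params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + eps)
            loss_trace.append(epoch_loss / n)
            if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:4d}  mse {loss_trace[-1]:.5f}")
        return PanAlleleResults(self, params, loss_trace)


class PanAlleleResults:
    """Fitted pan-allele model: weights, loss trace, prediction, persistence."""

    _FORMAT_VERSION = 1

    def __init__(
        self,
        model: PanAlleleANN | None,
        params: dict[str, np.ndarray],
        loss_trace: Sequence[float],
        *,
        config: PanModelConfig | None = None,
        pseudo_table: Mapping[str, str] | None = None,
        training_alleles: frozenset[str] | None = None,
    ) -> None:
        self.model = model
        self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        self.loss_trace = list(loss_trace)
        self.config = config if config is not None else model.config
        self.pseudo_table = (
            dict(pseudo_table) if pseudo_table is not None else dict(model.pseudo_table)
        )
        self.training_alleles = (
            training_alleles if training_alleles is not None else model.training_alleles
        )

    # -- prediction ---------------------------------------------------------

    def _predict_encoded(self, X: np.ndarray) -> np.ndarray:
        a1 = np.tanh(X @ self.params["W1"] + self.params["b1"])
        return _sigmoid(a1 @ self.params["W2"] + self.params["b2"]).ravel()

    def _pseudo_for(self, allele: str) -> str:
        try:
            return self.pseudo_table[allele]
        except KeyError:
            near = difflib.get_close_matches(allele, self.pseudo_table, n=3)
            raise DomainError(
                f"allele {allele!r} has no pseudo-sequence; nearest known: {near}"
            ) from None

    def predict_scores(
        self, peptides: Sequence[str], alleles: Sequence[str] | str
    ) -> np.ndarray:
        """Normalised-scale scores in [0, 1] (dropout disabled)."""
        if isinstance(alleles, str):
            alleles = [alleles] * len(peptides)
        if len(peptides) != len(alleles):
            raise DomainError("peptides and alleles must have equal length")
        X = _encode_dataset(
            list(peptides), [self._pseudo_for(a) for a in alleles], self.config
        )
        return self._predict_encoded(X)

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str] | str
    ) -> pd.DataFrame:
        """Prediction table with both the [0,1] score and the nM affinity."""
        if isinstance(alleles, str):
            alleles = [alleles] * len(peptides)
        scores = self.predict_scores(peptides, alleles)
        return pd.DataFrame(
            {
                "peptide": list(peptides),
                "allele": list(alleles),
                "score": scores,
                "ic50_nm": np.atleast_1d(inverse_transform(scores)),
            }
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Pan-allele ANN affinity regression results",
            "=" * 46,
            f"Observations:        {len(self.model.measurements) if self.model else 'n/a'}",
            f"Training alleles:    {len(self.training_alleles)}",
            f"Input features:      {cfg.n_features} ({cfg.input_positions} positions x 20)",
            f"Hidden units:        {cfg.hidden_units} ({cfg.activation})",
            f"Dropout (train):     {cfg.dropout}",
            f"Epochs / batch:      {cfg.epochs} / {cfg.batch_size}",
            f"Learning rate:       {cfg.learning_rate}",
            f"Seed:                {cfg.seed}",
            f"Final training MSE:  {self.loss_trace[-1]:.5f}"
            if self.loss_trace
            else "Final training MSE:  n/a",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise weights + config + allele list to a versioned JSON archive."""
        payload = {
            "format_version": self._FORMAT_VERSION,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "loss_trace": self.loss_trace,
            "training_alleles": sorted(self.training_alleles),
            "pseudo_table": self.pseudo_table,
            "pseudo_table_hash": _pseudo_table_hash(self.pseudo_table),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PanAlleleResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != cls._FORMAT_VERSION:
            raise DomainError("unsupported model archive version")
        return cls(
            None,
            {k: np.asarray(v) for k, v in payload["params"].items()},
            payload["loss_trace"],
            config=PanModelConfig(**payload["config"]),
            pseudo_table=payload["pseudo_table"],
            training_alleles=frozenset(payload["training_alleles"]),
        )


def leave_one_allele_out(
    measurements: Sequence[AffinityMeasurement],
    pseudo_table: Mapping[str, str],
    target_allele: str,
    config: PanModelConfig = PanModelConfig(),
):
    """Train without any record of ``target_allele``; evaluate on it.

    Measures generalisation to an unseen allele: the model can only reach
    the held-out allele through pseudo-sequence similarity to trained ones.
    Returns ``(results, report)`` where the report is the target allele's
    :class:`~mhcbench.metrics.MetricReport`.
    """
    from .metrics import benchmark_report

    held = [m for m in measurements if m.allele == target_allele]
    rest = [m for m in measurements if m.allele != target_allele]
    if not held:
        raise DomainError(f"target allele {target_allele!r} absent from data")
    if not rest:
        raise DomainError("no other allele remains after holding out the target")
    results = PanAlleleANN(rest, pseudo_table, config).fit()
    assert target_allele not in results.training_alleles

    pred = results.predict([m.peptide for m in held], [m.allele for m in held])
    pred_tbl = pd.DataFrame(
        {
            "peptide": pred["peptide"],
            "allele": pred["allele"],
            "predictor": "pan_ann_loo",
            "score": pred["score"],
            "predicted_nm": pred["ic50_nm"],
        }
    )
    reports, _ = benchmark_report(held, pred_tbl)
    report = next(r for r in reports if r.allele == target_allele)
    return results, report
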