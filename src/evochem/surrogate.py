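"""Surrogate fitness regression over generated-but-unevaluated molecules.

Most molecules an evolutionary campaign generates are never evaluated by the
expensive fitness function.  A cheap learned regressor — Morgan-fingerprint
features into a ridge regression with internal leave-one-out regularization
selection — predicts fitness (raw score or ligand efficiency) for the
remainder.  Two integration modes are supported:

* **combined**: each generation, the model nominates top-predicted unsampled
  molecules for true evaluation; these join the sampled-and-evaluated set and
  the model is retrained on the union.
* **clean**: after a campaign finishes, the model is trained on all archived
  evaluations and screens every unevaluated molecule; candidates beyond a
  score threshold are returned for re-evaluation.

An external graph-model backend (message-passing networks and kin) can be
plugged in behind the same train/predict contract.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.linear_model import RidgeCV
from sklearn.metrics import r2_score

logger = logging.getLogger(__name__)

_FP_BITS = 2048
_FP_RADIUS = 2


@dataclass
class SurrogateConfig:
    backend: str = "fingerprint_regressor"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    target: str = "raw_score"  # or "ligand_efficiency"
    screen_threshold: float = float("inf")
    top_k_for_reeval: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass
class SurrogateReport:
    r2_test: float
    n_train: int
    n_test: int
    n_val: int
    generation_span: tuple[int, ...] = ()

    def __post_init__(self):
        if self.r2_test > 1:
            raise ValueError("r2_test cannot exceed 1")


def _featurize(smiles: str) -> np.ndarray | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    fp = AllChem.GetMorganFingerprintAsBitVect(mol, _FP_RADIUS, nBits=_FP_BITS)
    arr = np.zeros(_FP_BITS, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


class SurrogateModel:
    """Fingerprint ridge regressor behind the surrogate contract."""

    def __init__(self, config: SurrogateConfig):
        self.config = config
        self._reg = RidgeCV(alphas=np.logspace(-3, 3, 13))
        self.n_train_ = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurrogateModel":
        self._reg.fit(X, y)
        self.n_train_ = len(y)
        return self

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return self._reg.predict(X)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "SurrogateModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _split_indices(n: int, fractions, rng_seed: int):
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    return order[:n_train], order[n_train : n_train + n_test], order[n_train + n_test :]


def train_surrogate(
    records: Sequence[tuple[str, float]],
    config: SurrogateConfig | None = None,
    generation_span: tuple[int, ...] = (),
) -> tuple[SurrogateModel, SurrogateReport]:
    """Fit the surrogate on (SMILES, target) records; report test-set R^2.

    The split (train/test/validation, default 80/10/10) is deterministic
    under the config seed.  The validation partition is held out and only
    its size is reported: the default backend needs no early stopping.
    """
    config = config or SurrogateConfig()
    if len(records) < 50:
        raise ValueError(f"need >= 50 records to train, got {len(records)}")
    feats, ys = [], []
    for smi, y in records:
        x = _featurize(smi)
        if x is not None:
            feats.append(x)
            ys.append(float(y))
    X = np.asarray(feats)
    y = np.asarray(ys)
    tr, te, va = _split_indices(len(y), config.split_fractions, config.rng_seed)
    model = SurrogateModel(config).fit(X[tr], y[tr])
    r2 = float(r2_score(y[te], model.predict_features(X[te]))) if len(te) > 1 else float("nan")
    report = SurrogateReport(
        r2_test=min(r2, 1.0) if np.isfinite(r2) else r2,
        n_train=len(tr),
        n_test=len(te),
        n_val=len(va),
        generation_span=tuple(generation_span),
    )
    return model, report


def predict(model: SurrogateModel, mols: Sequence[str]) -> list[float]:
    """One finite predicted score per parseable molecule; NaN sentinel otherwise."""
    out: list[float] = []
    batch, positions = [], []
    for i, smi in enumerate(mols):
        x = _featurize(smi)
        if x is None:
            warnings.warn(f"unparseable molecule skipped in prediction: {smi!r}")
            out.append(float("nan"))
        else:
            batch.append(x)
            positions.append(i)
            out.append(0.0)
    if batch:
        preds = model.predict_features(np.asarray(batch))
        for pos, p in zip(positions, preds):
            out[pos] = float(p)
    return out


def combined_mode_step(
    evaluated: Sequence[tuple[str, float]],
    unsampled: Sequence[str],
    model: SurrogateModel | None,
    evaluator: Callable[[str], float],
    config: SurrogateConfig | None = None,
) -> tuple[list[tuple[str, float]], SurrogateModel]:
    """One combined-mode round: nominate, truly evaluate, merge, retrain.

    With a model available, the ``top_k_for_reeval`` unsampled molecules by
    predicted score (docking convention: lowest first) are evaluated by the
    true fitness function and merged with the evaluated set; the model is
    then retrained on the union.  With no model yet (generation 1) the step
    reduces to training on the evaluated set alone.
    """
    config = config or SurrogateConfig()
    merged = list(evaluated)
    have = {s for s, _ in merged}
    if model is not None and config.top_k_for_reeval > 0 and unsampled:
        preds = predict(model, unsampled)
        ranked = sorted(
            (p, s) for p, s in zip(preds, unsampled) if np.isfinite(p) and s not in have
        )
        for _, smi in ranked[: config.top_k_for_reeval]:
            merged.append((smi, evaluator(smi)))
            have.add(smi)
    new_model, _ = train_surrogate(merged, config)
    return merged, new_model


def clean_mode_screen(
    unevaluated: Sequence[str],
    model: SurrogateModel,
    threshold: float,
) -> list[tuple[str, float]]:
    """Screen archived unevaluated molecules post-campaign.

    Returns (smiles, predicted score) for molecules with predicted score
    below ``threshold`` (docking convention), best first.
    """
    preds = predict(model, unevaluated)
    hits = [
        (smi, p) for smi, p in zip(unevaluated, preds) if np.isfinite(p) and p < threshold
    ]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits
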