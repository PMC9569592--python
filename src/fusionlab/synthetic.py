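"""Synthetic clinical + expression data with the dependency structure the
fusion analysis assumes.

The generator emulates a thyroid-nodule cohort: a binary histopathology
label (malignant/benign), raw clinical variables (sex, age, tumor size,
Bethesda cytology category II-VI) and a normalized log-scale expression
matrix.  The class signal is split between two channels:

* a *clinical* channel — Bethesda (and, ten times more weakly on the
  log-odds scale, age) drawn from proportional-odds models shifted by the
  true label;
* a *molecular* channel — informative genes shifted between classes, but
  driven by a per-sample molecular state ``L_mol`` that equals the label
  flipped with probability ``clinical_complementarity / 2``.

``clinical_complementarity`` therefore dials how much of the class signal
the genes can never see: at ``c`` the molecular channel recovers the label
with accuracy at most ``1 - c/2`` no matter how many genes are measured,
while the clinical channel is unaffected.  At ``c = 0`` the molecular
channel carries the full signal.

Pairwise gene correlation comes in two regimes: ``bimodal`` (two gene
blocks, correlation ``+block_rho`` within a block and ``-block_rho``
between blocks, via a single shared factor) and ``unimodal`` (weak
factor loadings, correlations concentrated near zero).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "generate_clinical",
    "generate_expression",
    "generate_dataset",
    "read_dataset",
]

SEX_LEVELS = ("F", "M")
BETHESDA_LEVELS = ("II", "III", "IV", "V", "VI")
LABEL_LEVELS = ("benign", "malignant")

#: proportional-odds cutpoints for the benign Bethesda distribution
#: (marginal roughly II .25 / III .30 / IV .25 / V .15 / VI .05, i.e.
#: mostly III-V as in FNAB series)
_BETHESDA_CUTPOINTS = (-1.0986, 0.2007, 1.3863, 2.9444)

#: cutpoints for the four age bands (<20, (20,45], (45,60], >60) giving a
#: benign marginal of roughly .05/.40/.35/.20
_AGE_CUTPOINTS = (-2.9444, -0.2007, 1.3863)

#: integer-year sampling ranges for each age band
_AGE_RANGES = ((14, 20), (21, 45), (46, 60), (61, 88))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the analysed cohort: 200 samples at 77/200
    malignant prevalence, a 163-gene panel with near-Gaussian pairwise
    correlations, ~15 informative genes, and a clinical channel whose
    Bethesda->label association gives a theoretical AUC ~= 0.90.
    """

    n_samples: int = 200
    prevalence: float = 77 / 200
    n_genes: int = 163
    n_informative: int = 15
    effect_size: float = 0.7
    correlation_regime: str = "unimodal"
    block_rho: float = 0.5
    clinical_signal: float = 3.5
    clinical_complementarity: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_samples, (int, np.integer)) or self.n_samples <= 0:
            raise ValueError(f"n_samples must be a positive count, got {self.n_samples!r}")
        if not (math.isfinite(self.prevalence) and 0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie strictly in (0, 1), got {self.prevalence!r}")
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be a positive count, got {self.n_genes!r}")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError(
                f"n_informative must satisfy 0 <= n_informative <= n_genes, got {self.n_informative!r}"
            )
        if not math.isfinite(self.effect_size):
            raise ValueError(f"effect_size must be finite, got {self.effect_size!r}")
        if self.correlation_regime not in ("unimodal", "bimodal"):
            raise ValueError(
                f"correlation_regime must be 'unimodal' or 'bimodal', got {self.correlation_regime!r}"
            )
        if not (math.isfinite(self.block_rho) and 0.0 <= self.block_rho < 1.0):
            raise ValueError(f"block_rho must lie in [0, 1), got {self.block_rho!r}")
        if not math.isfinite(self.clinical_signal):
            raise ValueError(f"clinical_signal must be finite, got {self.clinical_signal!r}")
        if not (
            math.isfinite(self.clinical_complementarity)
            and 0.0 <= self.clinical_complementarity <= 1.0
        ):
            raise ValueError(
                f"clinical_complementarity must lie in [0, 1], got {self.clinical_complementarity!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def _ordinal_sample(rng, n_levels, cutpoints, shift):
    """Draw from a proportional-odds model: latent logistic noise plus a
    per-sample shift, cut at fixed thresholds."""
    u = rng.logistic(size=len(shift))
    latent = u + shift
    codes = np.searchsorted(np.asarray(cutpoints), latent, side="left")
    return codes.clip(0, n_levels - 1)


def generate_clinical(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a raw clinical table (one row per sample, no missing values).

    Columns: ``sex`` (F/M), ``age`` (integer years), ``tumor_size`` (cm),
    ``bethesda`` (II-VI) and ``label`` (benign/malignant).  Bethesda is
    associated with the label at log-odds strength ``clinical_signal``;
    the age-band association is ten times weaker on the same scale; sex
    and tumor size are independent of the label.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_samples

    y = (rng.random(n) < config.prevalence).astype(int)

    beth_codes = _ordinal_sample(
        rng, 5, _BETHESDA_CUTPOINTS, config.clinical_signal * y.astype(float)
    )
    age_codes = _ordinal_sample(
        rng, 4, _AGE_CUTPOINTS, (config.clinical_signal / 10.0) * y.astype(float)
    )
    lo = np.array([_AGE_RANGES[c][0] for c in age_codes])
    hi = np.array([_AGE_RANGES[c][1] for c in age_codes])
    age = rng.integers(lo, hi + 1)

    sex = np.where(rng.random(n) < 0.82, "F", "M")  # typical FNAB sex skew
    tumor_size = np.round(np.exp(rng.normal(np.log(1.5), 0.6, size=n)), 2)
    tumor_size = np.maximum(tumor_size, 0.1)

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "sex": pd.Categorical(sex, categories=list(SEX_LEVELS)),
            "age": age.astype(int),
            "tumor_size": tumor_size,
            "bethesda": pd.Categorical(
                [BETHESDA_LEVELS[c] for c in beth_codes], categories=list(BETHESDA_LEVELS)
            ),
            "label": pd.Categorical(
                [LABEL_LEVELS[c] for c in y], categories=list(LABEL_LEVELS)
            ),
        }
    ).set_index("sample_id")


def generate_expression(config: GeneratorConfig, labels) -> pd.DataFrame:
    """Generate a samples x genes log-scale expression matrix.

    ``labels`` is a per-sample vector (benign/malignant or 0/1) of length
    ``config.n_samples``.  Informative genes are shifted by
    ``effect_size`` (alternating sign) between molecular states; the
    molecular state equals the label flipped per sample with probability
    ``clinical_complementarity / 2``.
    """
    config.validate()
    y = np.asarray(
        [1 if v in (1, "malignant", True) else 0 for v in np.asarray(labels).ravel()]
    )
    if len(y) != config.n_samples:
        raise ValueError(
            f"labels length {len(y)} does not match n_samples {config.n_samples}"
        )
    rng = _rng(config, 1)
    n, p = config.n_samples, config.n_genes

    flip = rng.random(n) < config.clinical_complementarity / 2.0
    l_mol = np.where(flip, 1 - y, y)

    noise = rng.standard_normal((n, p))
    if config.correlation_regime == "bimodal":
        # one shared factor, loadings +sqrt(rho) for block 1 and -sqrt(rho)
        # for block 2: correlation +rho within blocks, -rho between.
        f = rng.standard_normal(n)
        sign = np.ones(p)
        sign[p // 2 :] = -1.0
        x = math.sqrt(config.block_rho) * np.outer(f, sign) + math.sqrt(
            1.0 - config.block_rho
        ) * noise
    else:
        # weak random factor loadings: pairwise correlations centred at 0
        q = max(2, p // 20)
        loadings = rng.normal(0.0, 0.15, size=(q, p))
        factors = rng.standard_normal((n, q))
        common = factors @ loadings
        scale = np.sqrt(1.0 + (loadings**2).sum(axis=0))
        x = (common + noise) / scale

    shift = np.zeros(p)
    if config.n_informative:
        signs = np.where(np.arange(config.n_informative) % 2 == 0, 1.0, -1.0)
        shift[: config.n_informative] = config.effect_size * signs
    x = x + np.outer(l_mol.astype(float), shift)

    baseline = rng.uniform(4.0, 12.0, size=p)  # log2-microarray-like offsets
    x = x + baseline

    genes = [f"g{j:04d}" for j in range(p)]
    samples = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(x, index=pd.Index(samples, name="sample_id"), columns=genes)


def generate_dataset(config: GeneratorConfig, out_dir) -> dict:
    """Write clinical table, expression matrix, labels and a manifest to
    ``out_dir`` as comma-separated text; returns the file paths."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    clinical = generate_clinical(config)
    expr = generate_expression(config, clinical["label"])
    labels = clinical[["label"]]

    paths = {
        "clinical": out / "clinical.csv",
        "expression": out / "expression.csv",
        "labels": out / "labels.csv",
        "manifest": out / "manifest.json",
    }
    clinical.to_csv(paths["clinical"], float_format="%.6g")
    expr.to_csv(paths["expression"], float_format="%.10g")
    labels.to_csv(paths["labels"])
    manifest = {"config": asdict(config), "seed": int(config.seed)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_dataset(in_dir):
    """Read back a generated dataset; validates the manifest against its
    embedded config (seed mismatch is rejected)."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = manifest["config"]
    if int(manifest["seed"]) != int(cfg["seed"]):
        raise ValueError(
            f"manifest seed {manifest['seed']} disagrees with config seed {cfg['seed']}"
        )
    config = GeneratorConfig(**cfg)
    clinical = pd.read_csv(d / "clinical.csv", index_col="sample_id")
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("bethesda", BETHESDA_LEVELS),
        ("label", LABEL_LEVELS),
    ):
        clinical[col] = pd.Categorical(clinical[col], categories=list(levels))
    expr = pd.read_csv(d / "expression.csv", index_col="sample_id")
    labels = pd.read_csv(d / "labels.csv", index_col="sample_id")["label"]
    labels = pd.Series(
        pd.Categorical(labels, categories=list(LABEL_LEVELS)),
        index=labels.index,
        name="label",
    )
    return config, clinical, expr, labels


def bethesda_class_distributions(clinical_signal: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Bethesda category distributions for each class under the
    proportional-odds model (used for analytic AUC calibration)."""

    def dist(shift):
        cum = 1.0 / (1.0 + np.exp(-(np.asarray(_BETHESDA_CUTPOINTS) - shift)))
        cum = np.concatenate([[0.0], cum, [1.0]])
        return np.diff(cum)

    return dist(0.0), dist(clinical_signal)


def bethesda_auc(clinical_signal: float) -> float:
    """Theoretical AUC of the Bethesda category against the label."""
    p_b, p_m = bethesda_class_distributions(clinical_signal)
    cdf_b = np.concatenate([[0.0], np.cumsum(p_b)])[:-1]
    return float(np.sum(p_m * cdf_b) + 0.5 * np.sum(p_m * p_b))
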