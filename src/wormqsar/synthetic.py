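"""Synthetic descriptor matrices with planted signal and NOEC endpoints.

Emulates the statistical structure of the curated pesticide endpoint data:
a ~79:21 toxic:nontoxic imbalance, a handful of genuinely informative
descriptors (some with interaction/threshold-shaped effects that defeat
linear classifiers but not trees), redundant correlated blocks, constant
columns, and a sea of independent noise — at a desk scale of 449 compounds
by 300 descriptors rather than a full several-thousand-column 2D descriptor
table.

NOEC endpoints are drawn class-conditionally lognormal (toxic median
10 mg/kg, nontoxic median 1000 mg/kg) on the correct side of the 100 mg/kg
breakpoint, and a configurable fraction is emitted in the interval dialects
(``>0-10``, ``<100``, ``>100``, ``>10-100``, ``<100-inf``) so that every
curation rule can fire on generated data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import NOECRecord, parse_noec
from .data import NONTOXIC, TOXIC, DescriptorMatrix


@dataclass
class SyntheticConfig:
    n_compounds: int = 449
    n_descriptors: int = 300
    n_informative: int = 8
    n_nonlinear: int = 2  # subset of informative with XOR / threshold effects
    toxic_fraction: float = 355 / 449
    correlated_block_size: int = 5
    n_constant: int = 5
    noise_sd: float = 1.0
    effect_size: float = 1.0  # class mean shift, in noise-sd units
    interval_fraction: float = 0.15
    discard_fraction: float = 0.02  # emitted in breakpoint-straddling dialects
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative + self.n_constant > self.n_descriptors:
            raise ValueError(
                "invalid config: n_informative + n_constant <= n_descriptors violated "
                f"({self.n_informative} + {self.n_constant} > {self.n_descriptors})"
            )
        if not 0 < self.toxic_fraction < 1:
            raise ValueError("invalid config: 0 < toxic_fraction < 1 violated")
        if self.n_nonlinear > self.n_informative:
            raise ValueError("invalid config: n_nonlinear must not exceed n_informative")
        if self.noise_sd <= 0:
            raise ValueError("invalid config: noise_sd must be positive")
        for name in ("interval_fraction", "discard_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"invalid config: {name} must lie in [0, 1]")
        if min(self.n_compounds, self.n_descriptors) < 1:
            raise ValueError("invalid config: need at least one compound and one descriptor")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    descriptor_matrix: DescriptorMatrix
    noec_records: list[NOECRecord]
    truth: list[str]  # descriptor names planted as informative
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        """Write descriptor CSV, NOEC/label CSV and config JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.descriptor_matrix.X.to_csv(outdir / "descriptors.csv", index_label="compound_id")
        rows = []
        by_id = {r.compound_id: r for r in self.noec_records}
        for cid in self.descriptor_matrix.X.index:
            rec = by_id[cid]
            rows.append({"compound_id": cid, "noec": _render_noec(rec),
                         "label": int(self.descriptor_matrix.y.loc[cid])})
        pd.DataFrame(rows).to_csv(outdir / "noec.csv", index=False)
        self.config.to_json(outdir / "config.json")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _render_noec(rec: NOECRecord) -> str:
    if rec.kind == "real":
        return f"{rec.value:.6g}"
    if rec.upper == np.inf:
        return "<100-inf" if rec.lower == 0 else f">{rec.lower:g}"
    if rec.lower == 0:
        return f"<{rec.upper:g}"
    return f">{rec.lower:g}-{rec.upper:g}"


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a labeled descriptor matrix plus matching NOEC records.

    Deterministic under ``config.seed``. Linear informative descriptors get a
    class-conditional Gaussian mean shift of ``effect_size`` noise-sd units;
    nonlinear ones come as an XOR pair (jointly, not marginally, informative)
    and threshold-shaped effects; a correlated block of scaled copies of one
    latent factor emulates descriptor redundancy; constant columns have zero
    variance.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds

    y = (rng.random(n) < cfg.toxic_fraction).astype(int)
    sign = np.where(y == TOXIC, 1.0, -1.0)

    cols: dict[str, np.ndarray] = {}
    truth: list[str] = []
    n_linear = cfg.n_informative - cfg.n_nonlinear
    for j in range(n_linear):
        x = 0.5 * cfg.effect_size * cfg.noise_sd * sign + rng.normal(0, cfg.noise_sd, n)
        name = f"inf_lin_{j:02d}"
        cols[name] = x
        truth.append(name)

    # Nonlinear effects: the first two nonlinear slots form an XOR pair whose
    # product sign tracks the class while each margin is symmetric; further
    # slots get threshold effects (toxic compounds pushed above a cut point).
    k = 0
    while k < cfg.n_nonlinear:
        if cfg.n_nonlinear - k >= 2 and k == 0:
            s = rng.choice([-1.0, 1.0], size=n)
            amp = cfg.effect_size * cfg.noise_sd
            a = s * amp + rng.normal(0, 0.5 * cfg.noise_sd, n)
            b = s * sign * amp + rng.normal(0, 0.5 * cfg.noise_sd, n)
            cols["inf_xor_a"] = a
            cols["inf_xor_b"] = b
            truth += ["inf_xor_a", "inf_xor_b"]
            k += 2
        else:
            e = rng.normal(0, cfg.noise_sd, n)
            x = np.where(y == TOXIC, np.abs(e), e)
            name = f"inf_thr_{k:02d}"
            cols[name] = x
            truth.append(name)
            k += 1

    block = min(cfg.correlated_block_size,
                cfg.n_descriptors - cfg.n_informative - cfg.n_constant)
    latent = rng.normal(0, 1.0, n)
    for j in range(max(block, 0)):
        scale = rng.uniform(0.5, 2.0)
        cols[f"corr_{j:02d}"] = scale * latent + rng.normal(0, 0.1, n)

    for j in range(cfg.n_constant):
        cols[f"const_{j:02d}"] = np.full(n, float(j))

    n_noise = cfg.n_descriptors - len(cols)
    noise = rng.normal(0, 1.0, size=(n, n_noise))
    for j in range(n_noise):
        cols[f"noise_{j:03d}"] = noise[:, j]

    ids = [f"cmpd_{i:04d}" for i in range(n)]
    X = pd.DataFrame(cols, index=pd.Index(ids, name="compound_id"))
    matrix = DescriptorMatrix(X, pd.Series(y, index=X.index))

    records = _generate_noec_records(matrix, cfg, rng)
    return SyntheticDataset(matrix, records, truth, cfg)


def _generate_noec_records(matrix: DescriptorMatrix, cfg: SyntheticConfig,
                           rng: np.random.Generator) -> list[NOECRecord]:
    records: list[NOECRecord] = []
    for cid, lab in matrix.y.items():
        toxic = lab == TOXIC
        median = 10.0 if toxic else 1000.0
        value = _truncated_lognormal(rng, median, toxic)
        u = rng.random()
        if u < cfg.discard_fraction:
            text = ">10-100" if rng.random() < 0.5 else "<100-inf"
        elif u < cfg.discard_fraction + cfg.interval_fraction:
            if toxic:
                text = ">0-10" if value <= 10 else "<100"
            else:
                text = ">100"
        else:
            text = f"{value:.6g}"
        records.append(parse_noec(cid, text))
    return records


def _truncated_lognormal(rng: np.random.Generator, median: float, toxic: bool,
                         sigma_log10: float = 0.5, breakpoint: float = 100.0) -> float:
    """Lognormal NOEC draw rejected onto the generating class's side."""
    for _ in range(1000):
        v = 10 ** (np.log10(median) + sigma_log10 * rng.standard_normal())
        if (v < breakpoint) == toxic:
            return float(v)
    # Effectively unreachable; clamp as a last resort.
    return breakpoint / 2 if toxic else breakpoint


def univariate_auc(matrix: DescriptorMatrix) -> pd.Series:
    """Per-descriptor ROC AUC of the descriptor value against the label."""
    from sklearn.metrics import roc_auc_score

    if matrix.y is None:
        raise ValueError("labels required")
    out = {}
    y = matrix.y.to_numpy()
    for name in matrix.descriptor_names:
        x = matrix.X[name].to_numpy()
        if np.ptp(x) == 0:
            out[name] = 0.5
        else:
            out[name] = float(roc_auc_score(y, x))
    return pd.Series(out)
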