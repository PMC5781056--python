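"""End-to-end wiring: inputs -> features -> balance -> model -> report.

Every stage reads and writes the documented on-disk artifacts (feature
table TSV, balance report JSON, model JSON, CV report JSON), so stages are
independently runnable and testable.  ``RunConfig`` collects all knobs with
the published defaults: window flank 15, k-NN balancing starting at k=10,
SVM with C=1, gamma=0.01, tolerance=0.001, and 6/8/10-fold
cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .balance import LabeledDataset
from .balance import balance as run_balance
from .evaluate import cross_validate
from .features import build_dataset
from .io_formats import (
    attach_sites,
    read_fasta,
    read_feature_table,
    read_pssm,
    read_sites,
    read_structural_profile,
    write_feature_table,
)
from .model import SVMParams, SuccinylationSVM

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with the published defaults."""

    fasta: str = ""
    pssm_dir: str = ""
    spd3_dir: str = ""
    sites: str = ""
    out_dir: str = "succpred_run"
    flank: int = 15
    padding: str = "mirror-terminus"
    pssm_scale: str = "percent"
    use_bigram: bool = True
    k_start: int = 10
    ratio_max: float = 1.10
    k_max: int = 200
    do_balance: bool = True
    C: float = 1.0
    gamma: float = 0.01
    tolerance: float = 0.001
    folds: int = 10
    seed: int = 0
    balance_within_folds: bool = False
    log_level: str = "INFO"

    def svm_params(self) -> SVMParams:
        return SVMParams(C=self.C, gamma=self.gamma, tolerance=self.tolerance)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value config file (``key = value`` per line)."""
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: malformed config line {line!r}")
                key, raw = (t.strip() for t in line.split("=", 1))
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: dict) -> "RunConfig":
        defaults = cls()
        kwargs = {}
        for key, raw in values.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = (
                    raw if isinstance(raw, bool) else str(raw).lower() in ("1", "true", "yes")
                )
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = str(raw)
        return cls(**kwargs)


def load_inputs(config: RunConfig):
    """Read and align the four input files per protein."""
    records = read_fasta(config.fasta)
    if config.sites:
        records = attach_sites(records, read_sites(config.sites))
    pssms, profiles = {}, {}
    for rec in records:
        pssm_path = Path(config.pssm_dir) / f"{rec.id}.pssm"
        spd3_path = Path(config.spd3_dir) / f"{rec.id}.spd3"
        if not pssm_path.exists():
            raise FileNotFoundError(f"missing PSSM file for protein {rec.id!r}: {pssm_path}")
        if not spd3_path.exists():
            raise FileNotFoundError(f"missing SPD3 file for protein {rec.id!r}: {spd3_path}")
        pssms[rec.id] = read_pssm(pssm_path, scale_mode=config.pssm_scale, protein_id=rec.id)
        profiles[rec.id] = read_structural_profile(spd3_path, protein_id=rec.id)
    logger.info("loaded %d proteins", len(records))
    return records, pssms, profiles


def dataset_from_feature_table(path) -> LabeledDataset:
    df = read_feature_table(path)
    feature_cols = [c for c in df.columns if c.startswith("f")]
    ids = [f"{p}:{q}" for p, q in zip(df["protein_id"], df["position"])]
    return LabeledDataset(
        X=df[feature_cols].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
        ids=ids,
    )


def dataset_to_feature_table(data: LabeledDataset, path) -> None:
    ids, positions = zip(*(sid.rsplit(":", 1) for sid in data.ids))
    write_feature_table(path, ids, [int(p) for p in positions], data.y, data.X)


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> balance -> cross-validate -> train; return paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, pssms, profiles = load_inputs(config)
    data = build_dataset(
        records, pssms, profiles,
        flank=config.flank, padding=config.padding, use_bigram=config.use_bigram,
        prediction_mode=not config.sites,
    )
    logger.info(
        "featurized %d sites (%d positive, %d negative, %d features)",
        data.n_samples, data.n_positive, data.n_negative, data.X.shape[1],
    )
    features_path = out / "features.tsv"
    dataset_to_feature_table(data, features_path)

    artifacts = {"features": str(features_path)}
    if config.do_balance:
        data, report = run_balance(
            data, k_start=config.k_start, ratio_max=config.ratio_max, k_max=config.k_max
        )
        balance_path = out / "balance.json"
        with open(balance_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        artifacts["balance"] = str(balance_path)

    cv = cross_validate(
        data,
        n_folds=config.folds,
        params=config.svm_params(),
        seed=config.seed,
        balance_within_folds=config.balance_within_folds,
    )
    cv_path = out / "cv_report.json"
    cv.to_json(cv_path)
    artifacts["cv_report"] = str(cv_path)

    results = SuccinylationSVM(data=data, params=config.svm_params()).fit()
    model_path = out / "model.json"
    results.save(model_path)
    artifacts["model"] = str(model_path)

    config_path = out / "config.json"
    effective = asdict(config)
    with open(config_path, "w") as fh:
        json.dump(effective, fh, indent=2)
    artifacts["config"] = str(config_path)
    logger.info("pipeline complete; artifacts in %s", out)
    return artifacts
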