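"""End-to-end orchestration: curate -> fingerprint -> train -> explain.

A run directory holds the curated data, the fingerprint matrix with
its provenance map, one model bundle and evaluation report per
(metal, stoichiometry) dataset, the per-metal fragment-importance
tables, the cross-metal summary, and a machine-readable manifest
(config, seeds, versions, stage timings).  Stages are resumable: a
stage whose output files already exist in the run directory is
skipped on rerun.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import sklearn

from . import __version__
from .attribution import (
    filter_contributions,
    importance_report,
    kmeans_background,
    shapley_attribute,
)
from .data import (
    CurationCriteria,
    LigandRecord,
    SplitSpec,
    curate,
    read_records,
    write_records,
    write_rejections,
)
from .exceptions import LnqsprError, ParameterError
from .fingerprints import FingerprintSpec, detect_collisions, fingerprint_dataset
from .model import NetConfig, StabilityModel
from .synthetic import SyntheticSpec, generate


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    outdir: str
    input_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    curation: CurationCriteria = field(default_factory=CurationCriteria)
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    net: NetConfig = field(default_factory=NetConfig)
    metals: tuple[str, ...] | None = None  # None = all present
    stoichiometry: str = "1:1"
    k_background: int = 30
    attribution_mode: str = "sampled"
    budget: int = 512
    min_support: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ParameterError(
                "exactly one of input_csv and synthetic must be given"
            )
        # one master seed propagates to every stage
        self.split = dataclasses.replace(self.split, seed=self.seed)
        self.net = dataclasses.replace(self.net, seed=self.seed)
        if self.synthetic is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        return enc(self)


def _load_records(config: RunConfig) -> tuple[list[LigandRecord], list[dict]]:
    if config.input_csv is not None:
        return read_records(config.input_csv)
    return generate(config.synthetic).records, []


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stages_done: list[str] = []

    def stage(name: str):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.perf_counter()
                try:
                    result = fn(*a, **kw)
                except LnqsprError as exc:
                    raise type(exc)(f"stage {name}: {exc}") from exc
                timings[name] = time.perf_counter() - t0
                stages_done.append(name)
                return result

            return wrapped

        return deco

    # -- stage I/II: collect + curate ------------------------------------
    curated_path = out / "curated.csv"

    @stage("curate")
    def _curate() -> list[LigandRecord]:
        if curated_path.exists():
            records, _ = read_records(curated_path)
            return records
        raw, read_rej = _load_records(config)
        records, cur_rej = curate(raw, config.curation)
        records = [r for r in records if r.stoichiometry == config.stoichiometry]
        write_records(records, curated_path)
        write_rejections(read_rej + cur_rej, out / "rejections.csv")
        return records

    records = _curate()
    metals = config.metals or tuple(
        sorted({r.metal for r in records})
    )

    # -- stage III: fingerprints on the full curated dataset -------------
    @stage("fingerprint")
    def _fingerprint():
        smiles = sorted({r.smiles for r in records})
        fp = fingerprint_dataset(smiles, config.fingerprint)
        np.savetxt(out / "fingerprints.csv", fp.X, fmt="%d", delimiter=",")
        prov = {
            str(bit): {
                key: sorted({env.molecule_index for env in occs})
                for key, occs in envs.items()
            }
            for bit, envs in fp.provenance.items()
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))
        return smiles, fp

    smiles, fp = _fingerprint()
    row_of = {s: i for i, s in enumerate(smiles)}
    collisions = detect_collisions(fp)

    # -- stages IV-VI per metal ------------------------------------------
    tables = []
    eval_reports: dict[str, Any] = {}
    for metal in metals:
        sub = [r for r in records if r.metal == metal]
        mdir = out / f"model_{metal}_{config.stoichiometry.replace(':', 'to')}"
        mdir.mkdir(exist_ok=True)
        if len(sub) < max(config.split.n_folds, config.split.n_strata_bins) + 2:
            eval_reports[metal] = {
                "skipped": f"only {len(sub)} records for {metal}"
            }
            (mdir / "eval.json").write_text(json.dumps(eval_reports[metal]))
            continue

        @stage(f"train[{metal}]")
        def _train(sub=sub, mdir=mdir, metal=metal):
            y = np.array([r.logk for r in sub])
            X = fp.X[[row_of[r.smiles] for r in sub]].astype(float)
            model = StabilityModel(y, X, split_spec=config.split)
            res = model.fit(config.net)
            (mdir / "eval.json").write_text(json.dumps(res.report.to_dict(), indent=1))
            pd.DataFrame(
                {
                    "fold": np.concatenate(
                        [np.full(len(v), k) for k, (_, v) in enumerate(model.folds)]
                    ),
                    "record_index": np.concatenate([v for _, v in model.folds]),
                }
            ).to_csv(mdir / "folds.csv", index=False)
            with (mdir / "ensemble.pkl").open("wb") as fh:
                pickle.dump(res.ensemble, fh)
            return model, res

        model, res = _train()
        eval_reports[metal] = res.report.to_dict()

        @stage(f"explain[{metal}]")
        def _explain(model=model, res=res, sub=sub, metal=metal, mdir=mdir):
            Xtr = model.exog[model.train_idx]
            bg = kmeans_background(
                Xtr, k=min(config.k_background, len(Xtr)), seed=config.seed
            )
            attr = shapley_attribute(
                res.ensemble.predict,
                Xtr,
                bg,
                mode=config.attribution_mode,
                budget=config.budget,
                seed=config.seed,
                molecule_indices=np.array(
                    [row_of[sub[i].smiles] for i in model.train_idx]
                ),
            )
            table = filter_contributions(
                attr, fp, metal, min_support=config.min_support
            )
            table.to_csv(mdir / "fragments.csv", index=False)
            return table

        tables.append(_explain())

    # -- summary + manifest ----------------------------------------------
    @stage("report")
    def _report():
        non_empty = [t for t in tables if len(t)] or tables
        if non_empty:
            long, pivot = importance_report(non_empty)
            long.to_csv(out / "fragments_long.csv", index=False)
            pivot.to_csv(out / "fragments_pivot.csv")

    if tables:
        _report()

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "metals": list(metals),
        "n_records": len(records),
        "n_colliding_bits": len(collisions),
        "eval": eval_reports,
        "stages": stages_done,
        "timings_s": timings,
        "versions": {
            "lnqspr": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
        "notes": {
            "fingerprint_provenance": "computed on the full curated dataset",
            "explained_predictor": "ensemble-average function",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
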