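"""Configured, seeded, cached end-to-end runs.

A run executes the stages simulate -> distances -> dysbiosis -> shifts ->
temporal -> match -> network in dependency order inside one output
directory.  Every stage echoes its parameters; a machine-readable manifest
records package and library versions, the master seed, per-stage parameter
hashes and output-file hashes.  Stages whose parameter+upstream hash is
unchanged are reused from disk rather than recomputed.

Randomness is controlled by a single master seed fanned out to named
substreams per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import residualize, spearman_network
from .dissimilarity import bray_curtis, build_pair_sets, write_distance_tsv, write_pairs_tsv
from .dysbiosis import (
    DysbiosisClassifier,
    censored_exponential_mean,
    extract_episodes,
)
from .matching import completeness_report, match_cohort
from .profiles import read_metadata, read_profile_tsv, write_profile_tsv
from .shifts import ShiftDetector, attribute_shifts, call_shifts, shift_rate
from .synthetic import CohortConfig, simulate_cohort
from .temporal import blocked_permanova, fit_powerlaw, powerlaw_vs_flat_test

STAGES = ("simulate", "distances", "dysbiosis", "shifts", "temporal", "match", "network")


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs: generator config, stage toggles, parameters."""

    output_dir: str
    seed: int = 0
    cohort: dict = dataclasses.field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    reference_min_week: float = 20.0
    dysbiosis_percentile: float = 90.0
    shift_min_pairs: int = 30
    match_window: float = 2.0
    n_permutations: int = 999
    network_fdr: float = 0.05
    network_top_k: int = 300
    hub_degree: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Stage:
    """Disk-backed stage cache: skip recompute when the config hash matches."""

    def __init__(self, root: Path, name: str, params: dict, upstream: str = ""):
        self.dir = root / name
        self.dir.mkdir(parents=True, exist_ok=True)
        self.hash = _hash({"params": params, "upstream": upstream})
        self.marker = self.dir / ".hash"
        self.was_cached = self.cached()

    def cached(self) -> bool:
        return self.marker.exists() and self.marker.read_text().strip() == self.hash

    def commit(self) -> None:
        self.marker.write_text(self.hash)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "dysbiokit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    enabled = set(config.stages)
    for stage in enabled:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")

    ctx: dict = {}
    upstream = ""

    def record(stage: _Stage, name: str) -> None:
        manifest["stages"][name] = {
            "hash": stage.hash,
            "cached": stage.was_cached,
            "outputs": {
                p.name: _file_hash(p) for p in sorted(stage.dir.iterdir()) if p.name != ".hash"
            },
        }

    # -- simulate -----------------------------------------------------
    if "simulate" in enabled:
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": config.seed})
        st = _Stage(out, "simulate", cohort_cfg.to_dict())
        if not st.cached():
            cohort = simulate_cohort(cohort_cfg)
            write_profile_tsv(cohort.taxa_table, st.dir / "taxa.tsv")
            write_profile_tsv(cohort.coupled_table, st.dir / "coupled.tsv")
            cohort.metadata.to_csv(st.dir / "metadata.csv", index=False)
            with open(st.dir / "config.yaml", "w") as fh:
                yaml.safe_dump(cohort_cfg.to_dict(), fh)
            st.commit()
        ctx["taxa"] = read_profile_tsv(st.dir / "taxa.tsv", "MGX-taxa")
        ctx["coupled"] = read_profile_tsv(st.dir / "coupled.tsv", "MBX")
        ctx["metadata"] = read_metadata(st.dir / "metadata.csv")
        record(st, "simulate")
        upstream = st.hash

    # -- distances ----------------------------------------------------
    if "distances" in enabled:
        st = _Stage(out, "distances", {}, upstream)
        if not st.cached():
            dm = bray_curtis(ctx["taxa"])
            write_distance_tsv(dm, st.dir / "bray_curtis.tsv")
            pairs = build_pair_sets(dm, ctx["metadata"])
            write_pairs_tsv(pairs, st.dir / "pairs.tsv")
            st.commit()
            ctx["dm"], ctx["pairs"] = dm, pairs
        else:
            from skbio.stats.distance import DistanceMatrix

            raw = pd.read_csv(st.dir / "bray_curtis.tsv", sep="\t", index_col=0)
            ctx["dm"] = DistanceMatrix(raw.to_numpy(), ids=[str(c) for c in raw.columns])
            ctx["pairs"] = pd.read_csv(st.dir / "pairs.tsv", sep="\t")
        record(st, "distances")
        upstream = st.hash

    # -- dysbiosis ----------------------------------------------------
    if "dysbiosis" in enabled:
        params = {
            "min_week": config.reference_min_week,
            "percentile": config.dysbiosis_percentile,
        }
        st = _Stage(out, "dysbiosis", params, upstream)
        clf = DysbiosisClassifier(config.reference_min_week, config.dysbiosis_percentile)
        clf.fit(ctx["taxa"], ctx["metadata"])
        ctx["dysbiosis"] = clf
        if not st.cached():
            clf.result_().to_frame().to_csv(st.dir / "scores.tsv", sep="\t")
            episodes = extract_episodes(ctx["metadata"], clf.labels_)
            episodes.to_csv(st.dir / "episodes.tsv", sep="\t", index=False)
            summary = {"threshold": clf.threshold_}
            diag = ctx["metadata"].drop_duplicates("subject_id").set_index("subject_id")[
                "diagnosis"
            ]
            for group in ("UC", "CD"):
                for kind in ("duration", "interval"):
                    sub = episodes[
                        (episodes["kind"] == kind)
                        & (episodes["subject_id"].map(diag) == group)
                    ]
                    if len(sub) and (~sub["censored"]).any():
                        mean, se = censored_exponential_mean(sub)
                        summary[f"{group}_{kind}_mean_weeks"] = mean
                        summary[f"{group}_{kind}_se_weeks"] = se
            (st.dir / "summary.json").write_text(json.dumps(summary, indent=2))
            st.commit()
        record(st, "dysbiosis")
        upstream = st.hash

    # -- shifts -------------------------------------------------------
    if "shifts" in enabled:
        params = {"min_pairs": config.shift_min_pairs}
        st = _Stage(out, "shifts", params, upstream)
        if not st.cached():
            meta = ctx["metadata"]
            non_ibd = set(meta.loc[meta["diagnosis"] == "nonIBD", "sample_id"])
            ref_pairs = ctx["pairs"][
                ctx["pairs"]["sample_i"].isin(non_ibd)
                & ctx["pairs"]["sample_j"].isin(non_ibd)
            ]
            det = ShiftDetector(min_pairs=config.shift_min_pairs).fit(ref_pairs)
            det.curve_.to_frame().to_csv(st.dir / "threshold_curve.tsv", sep="\t", index=False)
            calls = call_shifts(ctx["pairs"], det.curve_, meta)
            calls = attribute_shifts(calls, ctx["taxa"])
            calls.to_csv(st.dir / "shift_calls.tsv", sep="\t", index=False)
            rates = {
                g: shift_rate(calls, ctx["pairs"], meta, group=g)
                for g in meta["diagnosis"].unique()
            }
            (st.dir / "rates.json").write_text(json.dumps(rates, indent=2))
            st.commit()
        record(st, "shifts")
        upstream = st.hash

    # -- temporal -----------------------------------------------------
    if "temporal" in enabled:
        params = {"n_perm": config.n_permutations}
        st = _Stage(out, "temporal", params, upstream)
        if not st.cached():
            meta = ctx["metadata"]
            rows = []
            intra = ctx["pairs"][ctx["pairs"]["relation"] != "inter"]
            diag = meta.set_index("sample_id")["diagnosis"]
            for group in meta["diagnosis"].unique():
                sub = intra[intra["sample_i"].map(diag) == group]
                sub = sub[sub["delta_weeks"] > 0]
                if len(sub) < 10:
                    continue
                fit = fit_powerlaw(sub["delta_weeks"], sub["dissimilarity"], group=group)
                f, p = powerlaw_vs_flat_test(fit)
                rows.append(
                    {
                        "test": "powerlaw_vs_flat",
                        "group": group,
                        "statistic": f,
                        "p": p,
                        "n": fit.n,
                        "scheme": "F",
                        "seed": config.seed,
                    }
                )
            for variable, scheme in (
                ("dysbiotic", "within-subject"),
                ("diagnosis", "subject-relabel"),
            ):
                res = blocked_permanova(
                    ctx["dm"], variable, meta, scheme=scheme,
                    n_perm=config.n_permutations, seed=config.seed,
                )
                rows.append(
                    {
                        "test": f"permanova[{variable}]",
                        "group": "all",
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "n": res.n,
                        "scheme": res.scheme,
                        "seed": config.seed,
                    }
                )
            pd.DataFrame(rows).to_csv(st.dir / "temporal_results.tsv", sep="\t", index=False)
            st.commit()
        record(st, "temporal")
        upstream = st.hash

    # -- match --------------------------------------------------------
    if "match" in enabled:
        params = {"window": config.match_window}
        st = _Stage(out, "match", params, upstream)
        meta_by_type = {
            "MGX": ctx["metadata"],
            "MBX": ctx["metadata"][
                ctx["metadata"]["sample_id"].isin([str(s) for s in ctx["coupled"].samples])
            ],
        }
        matched = match_cohort(meta_by_type, config.match_window)
        ctx["matched"] = matched
        if not st.cached():
            matched.to_csv(st.dir / "matched.tsv", sep="\t", index=False)
            completeness_report(meta_by_type, [("MGX", "MBX")]).to_csv(
                st.dir / "completeness.tsv", sep="\t", index=False
            )
            st.commit()
        record(st, "match")
        upstream = st.hash

    # -- network ------------------------------------------------------
    if "network" in enabled:
        params = {
            "fdr": config.network_fdr,
            "top_k": config.network_top_k,
            "hub_degree": config.hub_degree,
        }
        st = _Stage(out, "network", params, upstream)
        if not st.cached():
            meta = ctx["metadata"].copy()
            meta["dysbiotic"] = ctx["dysbiosis"].labels_[meta["sample_id"]].to_numpy()
            res_taxa = residualize(ctx["taxa"], meta, transform="arcsinsqrt")
            res_mbx = residualize(ctx["coupled"], meta, transform="log")
            matched = ctx["matched"]
            # align residual columns through the matched sets
            aligned = matched[
                matched["MGX_sample"].isin(res_taxa.columns)
                & matched["MBX_sample"].isin(res_mbx.columns)
            ]
            a = res_taxa[aligned["MGX_sample"]]
            b = res_mbx[aligned["MBX_sample"]]
            a.columns = [f"set{i}" for i in range(len(aligned))]
            b.columns = list(a.columns)
            net = spearman_network(
                {"MGX": a, "MBX": b},
                fdr_standard=config.network_fdr,
                top_k=config.network_top_k,
                hub_degree=config.hub_degree,
            )
            net.edges.to_csv(st.dir / "edges.tsv", sep="\t", index=False)
            nodes = pd.DataFrame(
                [
                    {"node": n, **d}
                    for n, d in net.graph.nodes(data=True)
                ]
            )
            nodes.to_csv(st.dir / "nodes.tsv", sep="\t", index=False)
            st.commit()
        record(st, "network")
        upstream = st.hash

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
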