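"""End-to-end analysis pipeline: biogeographic hypothesis comparison,
trait reconstruction with stochastic mapping, and pseudogene scanning,
driven by a YAML config.

Stage outputs are written as both TSV (human) and JSON (machine); every
report embeds the config hash and seed so a run can be reproduced from its
own output.  Reports are byte-deterministic given config + seed; wall-clock
times live only in the run log.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
import traceback
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dec import read_dispersal_model, read_geography
from .model_selection import HypothesisSpec, hypothesis_suite
from .pseudogene import (
    calls_to_tsv,
    read_alignment_fasta,
    scan_alignment,
    shared_deleterious,
    shared_report_json,
)
from .treeio import parse_newick
from .trait_mk import (
    MkModel,
    RootPrior,
    build_altitude_space,
    build_habitat_space,
    count_colonizations,
    fit_ard,
    fit_tied_rates,
    read_trait_table,
    simmap_event_log,
)

__all__ = ["RunConfig", "run", "load_config"]


class RunConfig:
    """Validated run configuration (see the README for the YAML schema).

    Sections are optional; only stages whose inputs are configured run.
    ``seed`` is mandatory as soon as any stochastic stage (trait simmap)
    is configured.
    """

    def __init__(self, data: dict, base_dir: Path):
        self.data = data
        self.base = Path(base_dir)
        self.seed = data.get("seed")
        self.tree_path = self._path(data.get("tree"))
        self.biogeo = data.get("biogeography")
        self.traits = data.get("traits") or {}
        self.pseudo = data.get("pseudogenes")
        if self.traits and self.seed is None:
            raise ValueError("config must set a seed when trait simmap stages run")
        for p in self._all_paths():
            if not p.exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def _path(self, rel) -> Path | None:
        return None if rel is None else (self.base / rel)

    def _all_paths(self):
        if self.tree_path:
            yield self.tree_path
        if self.biogeo:
            yield self._path(self.biogeo["geography"])
            for hyp in self.biogeo.get("hypotheses", []):
                if hyp.get("dispersal"):
                    yield self._path(hyp["dispersal"])
        for cfg in self.traits.values():
            yield self._path(cfg["table"])
        if self.pseudo:
            for a in self.pseudo.get("alignments", []):
                yield self._path(a)
            if self.pseudo.get("pairs"):
                yield self._path(self.pseudo["pairs"])

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(data, path.parent)


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed}


def _run_biogeo(config: RunConfig, out: Path) -> dict:
    tree = parse_newick(config.tree_path.read_text())
    bio = config.biogeo
    geog = read_geography(config._path(bio["geography"]).read_text())
    hyps = []
    for h in bio.get("hypotheses", [{"id": "M0", "assumption": "unguided"}]):
        dispersal = None
        if h.get("dispersal"):
            dispersal = read_dispersal_model(
                config._path(h["dispersal"]).read_text(), geog.universe
            )
        hyps.append(
            HypothesisSpec(
                id=h["id"],
                assumption=h.get("assumption", ""),
                dispersal=dispersal,
                w_free=bool(h.get("w_free", False)),
            )
        )
    table = hypothesis_suite(
        tree,
        geog,
        hyps,
        families=tuple(bio.get("families", ("DEC", "DIVALIKE", "BAYAREALIKE"))),
        max_range_size=bio.get("max_range_size"),
    )
    table.to_csv(out / "hypothesis_suite.tsv", sep="\t", index=False)
    payload = {**_stamp(config), "table": table.to_dict(orient="records")}
    (out / "hypothesis_suite.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"n_hypotheses": len(hyps), "best": table.loc[table["AICc"].idxmin(), "hypothesis"]}


def _trait_space(name: str, cfg: dict, tip_states: dict):
    kind = cfg.get("kind", name)
    if kind == "altitude":
        return build_altitude_space()
    if kind == "habitat":
        valleys = sorted(
            {
                s.split(":", 1)[1]
                for v in tip_states.values()
                for s in ([v] if isinstance(v, str) else v)
                if ":" in s
            }
        )
        return build_habitat_space(valleys or ["P1"])
    raise ValueError(f"unknown trait kind {kind!r} for section {name!r}")


def _root_prior(space, spec) -> RootPrior:
    if spec is None:
        return RootPrior.flat(space)
    if isinstance(spec, str):
        return RootPrior.fixed(space, spec)
    return RootPrior.restricted(space, spec)


def _run_trait(config: RunConfig, name: str, cfg: dict, out: Path) -> dict:
    tree = parse_newick(config.tree_path.read_text())
    tip_states = read_trait_table(config._path(cfg["table"]).read_text())
    space, mask = _trait_space(name, cfg, tip_states)
    prior = _root_prior(space, cfg.get("root_prior"))
    rate_mode = cfg.get("rate_mode", "tied" if space.classes else "ard")
    fit = fit_tied_rates if rate_mode == "tied" else fit_ard
    Q, lnL, k, score = fit(tree, tip_states, space, mask, prior)

    model = MkModel(tree, tip_states, space, prior)
    marg = model.marginals(Q)
    n_sims = int(cfg.get("n_sims", 1000))
    histories = model.sample_histories(Q, n_sims, np.random.default_rng(config.seed), mask=mask)
    report = {
        **_stamp(config),
        "trait": name,
        "rate_mode": rate_mode,
        "lnL": lnL,
        "k": k,
        "AICc": score,
        "Q": Q.tolist(),
        "states": list(space.labels),
        "n_sims": n_sims,
        "root_marginal": marg[tree.root].tolist(),
    }
    if space.classes is not None:
        counts = count_colonizations(histories, tree, space, mask=mask)
        report["colonizations"] = counts.summary()
    (out / f"trait_{name}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / f"trait_{name}_events.tsv").write_text(simmap_event_log(histories[:25], tree))
    return {"lnL": lnL, "n_sims": n_sims}


def _run_pseudogenes(config: RunConfig, out: Path) -> dict:
    pseudo = config.pseudo
    pairs = []
    if pseudo.get("pairs"):
        for line in config._path(pseudo["pairs"]).read_text().splitlines():
            if line.strip() and not line.startswith("#"):
                a, b = line.split()[:2]
                pairs.append((a, b))
    all_reports = {}
    n_calls = 0
    for apath in pseudo["alignments"]:
        path = config._path(apath)
        aln = read_alignment_fasta(path.read_text(), reference_id=pseudo.get("reference"))
        calls = scan_alignment(aln)
        n_calls += sum(len(v) for v in calls.values())
        (out / f"calls_{path.stem}.tsv").write_text(calls_to_tsv(calls))
        if pairs:
            usable = [p for p in pairs if p[0] in aln.sequences and p[1] in aln.sequences]
            reports = shared_deleterious(calls, usable)
            all_reports[path.stem] = json.loads(shared_report_json(reports))
    payload = {**_stamp(config), "genes": all_reports}
    (out / "shared_mutations.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"n_calls": n_calls, "n_genes": len(pseudo["alignments"])}


def run(config: RunConfig, out_dir) -> dict:
    """Execute every configured stage; independent stages continue past a
    failure.  Returns the run log (also written to ``run_log.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    if config.biogeo:
        stages.append(("biogeography", lambda: _run_biogeo(config, out)))
    for name, cfg in config.traits.items():
        stages.append((f"trait:{name}", lambda n=name, c=cfg: _run_trait(config, n, c, out)))
    if config.pseudo:
        stages.append(("pseudogenes", lambda: _run_pseudogenes(config, out)))

    log = {
        **_stamp(config),
        "version": __version__,
        "python": platform.python_version(),
        "stages": {},
        "ok": True,
    }
    for name, fn in stages:
        t0 = time.perf_counter()
        entry: dict = {}
        try:
            entry["result"] = fn()
            entry["status"] = "ok"
        except Exception as exc:  # stage isolation: record and continue
            entry["status"] = "error"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=5)
            log["ok"] = False
        entry["wall_seconds"] = round(time.perf_counter() - t0, 3)
        log["stages"][name] = entry
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
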