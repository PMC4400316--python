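"""End-to-end orchestration: simulate -> content -> sentiment -> geo-temporal -> network.

A :class:`RunConfig` (loadable from YAML) describes the inputs (a corpus file
or a generator configuration), which stages to run, the output directory and
every tunable parameter that a stage consumes (feature count, Louvain
resolution, arbitration rule).  ``run_pipeline`` executes the enabled stages
in order, writes CSV/JSON reports per stage plus a machine-readable
``summary.json``, and is deterministic given the seed.  Every value in the
summary is computed by the underlying module operations — the pipeline adds
no computation of its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from . import corpus as corpus_mod
from . import geotemporal, network, sentiment, synth, termgraph

log = logging.getLogger("painstream")

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "painstream_out"
    corpus_path: Optional[str] = None  # if None, a synthetic corpus is generated
    lexicon_path: Optional[str] = None
    emoticon_path: Optional[str] = None
    covariates_path: Optional[str] = None
    query_term: str = "pain"
    # stage toggles
    run_content: bool = True
    run_sentiment: bool = True
    run_geotemporal: bool = True
    run_network: bool = True
    # parameters
    k_features: int = 2000
    resolution: float = 1.0
    arbitration: str = "rule_first"
    top_k: int = 25
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)

    def validate(self) -> None:
        if self.arbitration not in ("rule_first", "vote"):
            raise ValueError(f"unknown arbitration {self.arbitration!r}")
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML mapping (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    gen_raw = raw.pop("generator", {})
    net_raw = gen_raw.pop("network", {}) if isinstance(gen_raw, dict) else {}
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    gen_allowed = set(synth.GeneratorConfig.__dataclass_fields__)
    bad = set(gen_raw) - gen_allowed
    if bad:
        raise ValueError(f"unknown generator keys: {sorted(bad)}")
    cities = gen_raw.pop("cities", None)
    gen_kwargs = dict(gen_raw)
    if cities is not None:
        gen_kwargs["cities"] = tuple(synth.CityConfig(**c) for c in cities)
    if "topic_communities" in gen_kwargs:
        gen_kwargs["topic_communities"] = tuple(tuple(c) for c in gen_kwargs["topic_communities"])
    if "words_per_tweet" in gen_kwargs:
        gen_kwargs["words_per_tweet"] = tuple(gen_kwargs["words_per_tweet"])
    if net_raw:
        gen_kwargs["network"] = synth.NetworkConfig(**net_raw)
    cfg = RunConfig(**raw, generator=synth.GeneratorConfig(**gen_kwargs))
    cfg.validate()
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _get_corpus(cfg: RunConfig, out: Path):
    if cfg.corpus_path:
        corpus = corpus_mod.parse_tweets(cfg.corpus_path, query_term=cfg.query_term)
        truth = None
    else:
        gen = replace(cfg.generator, seed=cfg.seed, query_term=cfg.query_term)
        corpus, truth = synth.generate_corpus(gen)
        corpus_mod.write_tweets(corpus, out / "corpus.jsonl")
        truth.save(out / "ground_truth.json")
    reduced = corpus_mod.deduplicate(corpus)
    offsets = synth.city_offsets(cfg.generator)
    try:
        reduced = corpus_mod.localize_timestamps(reduced, offsets)
    except KeyError:
        log.warning("no UTC offsets for some cities; local-hour analysis disabled")
    return reduced, truth


@_stage("content")
def _content(cfg: RunConfig, reduced, out: Path, summary: dict) -> None:
    streams = corpus_mod.tokenize_corpus(reduced)
    graph = termgraph.build_cooccurrence_graph(streams)
    part = termgraph.louvain_communities(graph, seed=cfg.seed, resolution=cfg.resolution)
    termgraph.write_top_terms_csv(graph, cfg.top_k, out / "top_terms.csv")
    termgraph.write_top_edges_csv(graph, cfg.top_k, out / "top_edges.csv")
    graph.to_graphml(out / "term_graph.graphml", part)
    summary["content"] = {
        "n_terms": graph.n_nodes,
        "n_edges": graph.n_edges,
        "n_communities": part.n_communities,
        "modularity": round(part.q, 6),
        "top10_community_fraction": round(
            termgraph.community_size_report(part, min(10, part.n_communities)), 6),
        "top_terms": termgraph.top_terms(graph, min(cfg.top_k, graph.n_nodes)),
        "top_edges": termgraph.top_edges(graph, min(cfg.top_k, graph.n_edges))
        if graph.n_edges else [],
    }


@_stage("sentiment")
def _sentiment(cfg: RunConfig, reduced, truth, out: Path, summary: dict):
    if cfg.lexicon_path:
        lex = sentiment.Lexicon.from_tsv(cfg.lexicon_path, cfg.emoticon_path)
    else:
        lex = sentiment.load_default_lexicon()
    scoring_streams = corpus_mod.tokenize_corpus(reduced, keep_query=True)
    labels = [tw.label for tw in reduced]
    model = None
    if all(l in ("positive", "negative") for l in labels) and len(set(labels)) == 2:
        model = sentiment.train_nb(scoring_streams, labels, k_features=cfg.k_features)
        model.to_json(out / "nb_model.json")
    results = sentiment.classify_corpus(scoring_streams, lex, model,
                                        arbitration=cfg.arbitration)
    pct = sentiment.percent_positive(results)
    summary["sentiment"] = {
        "n_tweets": len(results),
        "percent_positive": round(pct, 2),
        "rule_decided": sum(1 for r in results if r.source == "rule"),
        "nb_decided": sum(1 for r in results if r.source == "nb"),
    }
    if truth is not None:
        correct = sum(
            1 for tw, r in zip(reduced, results)
            if truth.tweet_polarity.get(tw.id) == r.hybrid_polarity)
        summary["sentiment"]["accuracy_vs_truth"] = round(correct / len(results), 4)
    return results


@_stage("geotemporal")
def _geotemporal(cfg: RunConfig, reduced, results, out: Path, summary: dict) -> None:
    positives = [r.hybrid_polarity == "positive" for r in results]
    by_city = geotemporal.proportion_by_group([tw.city for tw in reduced], positives, "city")
    by_city.table.to_csv(out / "city_sentiment.csv", index=False)
    block: dict = {"by_city": {
        "median_percent": round(by_city.median_percent, 2),
        "n_groups": len(by_city),
    }}
    if len(by_city) >= 2:
        stat, df, p = geotemporal.homogeneity_test(by_city)
        block["by_city"].update(chi2=round(stat, 4), df=df, p=float(p))
    if all(tw.local_hour is not None for tw in reduced):
        by_hour = geotemporal.proportion_by_group(
            [tw.local_hour for tw in reduced], positives, "hour")
        by_hour.table.to_csv(out / "hour_sentiment.csv", index=False)
        block["by_hour"] = {
            "median_percent": round(by_hour.median_percent, 2),
            "n_groups": len(by_hour),
        }
        if len(by_hour) >= 2:
            stat, df, p = geotemporal.homogeneity_test(by_hour)
            block["by_hour"].update(chi2=round(stat, 4), df=df, p=float(p))
    if cfg.covariates_path:
        cov = geotemporal.load_covariates(cfg.covariates_path)
        corrs = geotemporal.correlate_covariates(by_city, cov)
        block["covariate_correlations"] = [
            {"variable": c.variable, "rho": round(c.rho, 3), "p": round(c.p, 4)}
            for c in corrs
        ]
    summary["geotemporal"] = block


@_stage("network")
def _network(cfg: RunConfig, out: Path, summary: dict) -> None:
    gen = replace(cfg.generator, seed=cfg.seed + 1, query_term=cfg.query_term)
    if gen.network.topology == "none":
        gen = replace(gen, network=replace(gen.network, topology="planted_partition"))
    mention_corpus, truth = synth.generate_mention_corpus(gen)
    corpus_mod.write_tweets(mention_corpus, out / "mention_corpus.jsonl")
    edges = network.extract_mention_edges(mention_corpus)
    net = network.build_network(edges, query_term=cfg.query_term)
    metrics = network.network_metrics(net, seed=cfg.seed)
    net.to_graphml(out / "mention_network.graphml")
    pct, n_inv, n_tot = network.involvement_report([mention_corpus])
    deg = network.degree_stats(net)
    summary["network"] = {
        "metrics": asdict(metrics),
        "degree_summary": deg["summary"],
        "involvement_percent": pct,
        "involved": n_inv,
        "total": n_tot,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns (and writes) the summary dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "query_term": cfg.query_term,
                     "parameters": {"k_features": cfg.k_features,
                                    "resolution": cfg.resolution,
                                    "arbitration": cfg.arbitration,
                                    "negation_window": sentiment.NEGATION_WINDOW}}
    reduced, truth = _get_corpus(cfg, out)
    summary["corpus"] = {"n_tweets": len(reduced), "provenance": reduced.provenance}
    results = None
    if cfg.run_content:
        _content(cfg, reduced, out, summary)
    if cfg.run_sentiment:
        results = _sentiment(cfg, reduced, truth, out, summary)
    if cfg.run_geotemporal:
        if results is None:
            results = _sentiment(cfg, reduced, truth, out, summary)
        _geotemporal(cfg, reduced, results, out, summary)
    if cfg.run_network:
        _network(cfg, out, summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True),
                                      "utf-8")
    return summary
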