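"""End-to-end pipeline composition and run metadata.

``run_pipeline`` chains read → descriptor filter → (language filter) →
lemmatize → collect seed sentences → frequencies → network → Louvain →
cluster ranking, attaching the stage name to any error so failures are
attributable.  When an output directory is given it writes the
frequency CSV, pair-count CSV, GEXF network, cluster report and a JSON
run-metadata file; all outputs are byte-reproducible from the inputs
plus ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

from . import __version__
from .cooccurrence import (CooccurrenceTable, collect_seed_sentences,
                           compute_frequencies)
from .corpus import Corpus, RunConfig, SeedLexicon, read_corpus
from .errors import PipelineStageError
from .gexf import write_gexf
from .network import (ClusterInfo, Partition, SemanticNetwork, build_network,
                      louvain, rank_clusters)
from .preprocessing import (LemmatizerBackend, RuleLemmatizer,
                            filter_by_descriptors, lemmatize_corpus)
from .tables import write_cluster_report, write_frequency_csv, write_pairs_csv

logger = logging.getLogger(__name__)

OUTPUT_FILES = {
    "frequencies": "frequencies.csv",
    "pairs": "pairs.csv",
    "network": "network.gexf",
    "clusters": "clusters.csv",
    "metadata": "run_metadata.json",
}


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    table: CooccurrenceTable
    network: SemanticNetwork
    partition: Partition
    clusters: tuple[ClusterInfo, ...]
    run_metadata: dict


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_pipeline(
    corpus_path: str | Path | None,
    schema_map: Mapping[str, str] | None,
    config: RunConfig,
    lexicon: SeedLexicon | None = None,
    *,
    channel: str = "social",
    corpus: Corpus | None = None,
    backend: LemmatizerBackend | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a corpus file (or an in-memory corpus)."""
    lexicon = lexicon or SeedLexicon()
    backend = backend or RuleLemmatizer()

    if corpus is None:
        corpus = _stage(
            "read_corpus", read_corpus, corpus_path, schema_map, channel,
            date_format=config.date_format,
        )
    n_in = len(corpus)
    corpus = _stage("filter_by_descriptors", filter_by_descriptors, corpus, lexicon)
    n_filtered = len(corpus)
    if config.language_filter is not None:
        keep = [d for d in corpus if d.language == config.language_filter]
        corpus = corpus.subset(keep, f"language={config.language_filter}")
    sentences = _stage(
        "lemmatize_corpus", lemmatize_corpus, corpus, backend, lexicon, config
    )
    seed_sentences = _stage("collect_seed_sentences", collect_seed_sentences, sentences)
    table = _stage("compute_frequencies", compute_frequencies, seed_sentences, lexicon)
    network = _stage("build_network", build_network, table, lexicon, config)
    partition = _stage("louvain", louvain, network, config)
    clusters = tuple(_stage("rank_clusters", rank_clusters, partition, network))

    run_metadata = {
        "seednet_version": __version__,
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(RunConfig)
        },
        "rng_seed": config.rng_seed,
        "lexicon": {
            "seed_lemmas": sorted(lexicon.seed_lemmas),
            "descriptor_terms": sorted(lexicon.descriptor_terms),
            "extra_seed_surface_forms": dict(
                sorted(lexicon.extra_seed_surface_forms.items())
            ),
        },
        "backend": backend.name,
        "counts": {
            "documents_in": n_in,
            "documents_after_filter": n_filtered,
            "documents_analyzed": len(corpus),
            "sentences": len(sentences),
            "seed_sentences": table.n_seed_sentences,
            "nodes": len(network.nodes),
            "edges": len(network.edges),
            "clusters": partition.n_communities,
        },
        "modularity": partition.modularity,
    }
    logger.info("pipeline counts: %s", run_metadata["counts"])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_frequency_csv(table, outdir / OUTPUT_FILES["frequencies"])
        write_pairs_csv(table, outdir / OUTPUT_FILES["pairs"])
        write_gexf(network, partition, outdir / OUTPUT_FILES["network"])
        write_cluster_report(clusters, outdir / OUTPUT_FILES["clusters"])
        (outdir / OUTPUT_FILES["metadata"]).write_text(
            json.dumps(run_metadata, ensure_ascii=False, sort_keys=True, indent=1)
            + "\n",
            encoding="utf-8",
        )
    return PipelineResult(
        table=table, network=network, partition=partition,
        clusters=clusters, run_metadata=run_metadata,
    )
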