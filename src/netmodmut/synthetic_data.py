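"""Seeded synthetic cohorts with a planted, survival-prognostic module.

The generator emulates the inputs the pipeline consumes: a gene annotation
laid out on a small set of chromosomes, an interaction network in which a
chosen module is wired as a near-clique over a random background, and two
independent cohorts (discovery / validation) of per-sample copy-number
segments plus survival records.  Gene states are drawn per gene and sample
(module genes at elevated gain/loss rates), contiguous same-state genes are
emitted as one segment that passes the quality filter, and decoy segments
that fail it are sprinkled in.  Survival times are exponential with
log-hazard proportional to the planted module's mutation score, with
independent uniform censoring.

Everything is driven by one integer seed; identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cna_matrix import CNASegment, GeneInterval
from .mutation_scores import gene_frequencies


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-cohort experiment.

    Defaults describe a scaled-down two-cohort design: 300 samples per
    cohort over a 200-gene universe with an 8-gene planted module mutated
    in 45% of samples (gain:loss 2:1) against an 8% background, a sparse
    background interactome (600 edges, mean degree 6) with the module wired
    as a clique, and exponential survival whose log-hazard rises by
    ``survival_effect`` per unit of the module's mutation score.
    """

    n_samples: int = 300
    n_genes: int = 200
    n_chromosomes: int = 4
    gene_length: int = 10_000
    gene_spacing: int = 5_000

    network_model: str = "gnm"        # "gnm" or "small_world"
    n_background_edges: int = 600
    small_world_k: int = 6
    small_world_p: float = 0.1
    module_clique_p: float = 1.0      # probability of each within-module edge

    module_size: int = 8
    module_gain_rate: float = 0.30
    module_loss_rate: float = 0.15
    background_gain_rate: float = 0.05
    background_loss_rate: float = 0.03
    # Real gene-level CNA frequencies are heterogeneous in both magnitude and
    # gain/loss composition (a gene tends to sit in recurrent amplicons OR in
    # recurrently deleted regions); with identical background rates every
    # gene-pair cosine similarity would degenerate to ~1.  Each background
    # gene draws a total rate uniform on mean*(1 -+ spread) and a gain share
    # from Beta(conc, conc) (conc < 1: mostly gain- or loss-dominant genes),
    # fixed per gene and shared by both cohorts.
    background_rate_spread: float = 0.8
    background_gain_share_conc: float = 0.3

    probes_per_gene: int = 12
    decoys_per_sample: int = 2

    baseline_hazard: float = 0.05
    survival_effect: float = 1.0      # log-hazard per unit of mutation score
    follow_up_max: float = 40.0       # uniform censoring horizon

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "module_gain_rate",
            "module_loss_rate",
            "background_gain_rate",
            "background_loss_rate",
            "module_clique_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_gain_rate + self.module_loss_rate > 1.0:
            raise ValueError("module gain + loss rate exceeds 1")
        if self.background_gain_rate + self.background_loss_rate > 1.0:
            raise ValueError("background gain + loss rate exceeds 1")
        if not 0.0 <= self.background_rate_spread <= 1.0:
            raise ValueError("background_rate_spread must lie in [0, 1]")
        bg_max = (self.background_gain_rate + self.background_loss_rate) * (
            1.0 + self.background_rate_spread
        )
        if bg_max > 1.0:
            raise ValueError("background rate spread pushes total rate above 1")
        if self.module_size > self.n_genes:
            raise ValueError("planted module larger than the gene universe")


@dataclass
class CohortBundle:
    """Synthetic inputs for one cohort."""

    cohort_id: str
    segments: list[CNASegment]
    survival: pd.DataFrame          # index sample, columns time/event
    states: pd.DataFrame            # ground-truth samples x genes matrix
    scores: pd.Series               # planted-module mutation scores


@dataclass
class SimBundle:
    """Everything the two-cohort experiment shares plus both cohorts."""

    config: SimConfig
    annotation: list[GeneInterval]
    network: nx.Graph
    module_genes: list[str]
    discovery: CohortBundle
    validation: CohortBundle
    gain_rates: pd.Series | None = None   # per-gene true gain probability
    loss_rates: pd.Series | None = None   # per-gene true loss probability


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_annotation(config: SimConfig) -> list[GeneInterval]:
    """Non-overlapping gene intervals laid out evenly across chromosomes."""
    if config.n_genes < 1 or config.n_chromosomes < 1:
        raise ValueError("need positive gene and chromosome counts")
    if config.gene_length < 1 or config.gene_spacing < 0:
        raise ValueError("infeasible gene layout")
    ids = _gene_ids(config.n_genes)
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    out = []
    for i, gid in enumerate(ids):
        chrom = str(i // per_chrom + 1)
        slot = i % per_chrom
        start = 1 + slot * (config.gene_length + config.gene_spacing)
        out.append(GeneInterval(gid, chrom, start, start + config.gene_length - 1))
    return out


def simulate_network(
    config: SimConfig, annotation: list[GeneInterval], module_genes: list[str], seed: int
) -> nx.Graph:
    """Background random graph plus a near-clique over the planted module."""
    ids = [g.gene_id for g in annotation]
    if not set(module_genes) <= set(ids):
        raise ValueError("module genes must belong to the annotation")
    n = len(ids)
    max_edges = n * (n - 1) // 2
    if config.n_background_edges > max_edges:
        raise ValueError("requested more background edges than a simple graph holds")
    rng = np.random.default_rng(seed)
    if config.network_model == "gnm":
        bg = nx.gnm_random_graph(n, config.n_background_edges, seed=int(rng.integers(2**31 - 1)))
    elif config.network_model == "small_world":
        bg = nx.watts_strogatz_graph(
            n, config.small_world_k, config.small_world_p, seed=int(rng.integers(2**31 - 1))
        )
    else:
        raise ValueError(f"unknown network model {config.network_model!r}")
    g = nx.relabel_nodes(bg, dict(enumerate(ids)))
    for i, u in enumerate(module_genes):
        for v in module_genes[i + 1 :]:
            if config.module_clique_p >= 1.0 or rng.random() < config.module_clique_p:
                g.add_edge(u, v)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def gene_rate_profiles(
    config: SimConfig, module_mask: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (gain, loss) state probabilities shared by both cohorts.

    Module genes use the configured module rates.  Background genes draw a
    total rate uniform on mean * (1 -+ spread) and split it by a uniform
    gain share, so frequency vectors vary in magnitude and direction the
    way real gene-level CNA frequencies do.
    """
    rng = np.random.default_rng(seed)
    m = len(module_mask)
    bg_mean = config.background_gain_rate + config.background_loss_rate
    total = rng.uniform(
        bg_mean * (1.0 - config.background_rate_spread),
        bg_mean * (1.0 + config.background_rate_spread),
        size=m,
    )
    conc = config.background_gain_share_conc
    share = rng.beta(conc, conc, size=m)
    p_gain = np.where(module_mask, config.module_gain_rate, total * share)
    p_loss = np.where(module_mask, config.module_loss_rate, total * (1.0 - share))
    return p_gain, p_loss


def _draw_states(
    p_gain: np.ndarray, p_loss: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample, per-gene -1/0/+1 states with per-gene rates."""
    u = rng.random((n_samples, len(p_gain)))
    states = np.zeros_like(u, dtype=np.int8)
    states[u < p_gain] = 1
    states[(u >= p_gain) & (u < p_gain + p_loss)] = -1
    return states


def _states_to_segments(
    sample_id: str,
    states_row: np.ndarray,
    annotation: list[GeneInterval],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[CNASegment]:
    """Run-length encode per-gene states into quality-passing segments.

    Neutral runs are emitted too (real SEG files carry them); decoy
    segments that fail the length or probe filter are appended with random
    states so the quality filter has something to remove.
    """
    code_state = {1: "GAIN", -1: "HETD", 0: "NEUT"}
    # refine gains/losses into the 5-level vocabulary at random
    segs: list[CNASegment] = []
    by_chrom: dict[str, list[tuple[int, GeneInterval]]] = {}
    for i, g in enumerate(annotation):
        by_chrom.setdefault(g.chrom, []).append((i, g))
    for chrom, genes in by_chrom.items():
        run_start = 0
        idx = [i for i, _ in genes]
        vals = states_row[idx]
        k = 0
        while k < len(genes):
            j = k
            while j + 1 < len(genes) and vals[j + 1] == vals[k]:
                j += 1
            first, last = genes[k][1], genes[j][1]
            state = code_state[int(vals[k])]
            if state == "GAIN" and rng.random() < 0.3:
                state = "AMP"
            elif state == "HETD" and rng.random() < 0.3:
                state = "HOMD"
            segs.append(
                CNASegment(
                    sample_id,
                    chrom,
                    first.start,
                    last.end,
                    config.probes_per_gene * (j - k + 1),
                    state,
                )
            )
            k = j + 1
        del run_start
    for d in range(config.decoys_per_sample):
        g = annotation[int(rng.integers(len(annotation)))]
        state = ["GAIN", "HETD", "AMP", "HOMD"][int(rng.integers(4))]
        if d % 2 == 0:
            # too short
            start = g.start + int(rng.integers(max(g.end - g.start - 2000, 1)))
            segs.append(CNASegment(sample_id, g.chrom, start, start + 1999, 30, state))
        else:
            # too few probes
            segs.append(CNASegment(sample_id, g.chrom, g.start, g.end, 5, state))
    return segs


def simulate_cohort(
    config: SimConfig,
    annotation: list[GeneInterval],
    module_genes: list[str],
    cohort_id: str,
    seed: int,
    rates: tuple[np.ndarray, np.ndarray] | None = None,
) -> CohortBundle:
    """One cohort: segments, ground-truth states and module-driven survival.

    Survival times are exponential with hazard
    baseline_hazard * exp(effect * (score_j - mean score)), where score_j
    is the planted module's mutation score computed from the cohort's own
    realized matrix; censoring is uniform on [0, follow_up_max].  The score
    is centred so that the configured baseline describes an average sample.
    """
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in annotation]
    module_mask = np.isin(np.array(ids), np.array(list(module_genes)))
    if rates is None:
        rates = gene_rate_profiles(config, module_mask, seed=seed)
    states = _draw_states(rates[0], rates[1], config.n_samples, rng)
    width = len(str(config.n_samples))
    sample_ids = [f"{cohort_id}S{j + 1:0{width}d}" for j in range(config.n_samples)]
    matrix = pd.DataFrame(states, index=pd.Index(sample_ids, name="sample"), columns=ids)

    segments: list[CNASegment] = []
    for j, sid in enumerate(sample_ids):
        segments.extend(_states_to_segments(sid, states[j], annotation, config, rng))

    freqs = gene_frequencies(matrix)
    f = freqs.loc[list(module_genes), "heat"].to_numpy()
    scores = pd.Series(
        np.abs(matrix[list(module_genes)].to_numpy()) @ f, index=matrix.index, name="score"
    )
    hazard = config.baseline_hazard * np.exp(
        config.survival_effect * (scores.to_numpy() - scores.to_numpy().mean())
    )
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, config.follow_up_max, size=config.n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(sample_ids, name="sample")
    )
    return CohortBundle(
        cohort_id=cohort_id,
        segments=segments,
        survival=survival,
        states=matrix,
        scores=scores,
    )


def make_two_cohorts(config: SimConfig) -> SimBundle:
    """Discovery and validation cohorts sharing annotation, network and module."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=4)
    annotation = simulate_annotation(config)
    ids = [g.gene_id for g in annotation]
    module_genes = sorted(
        map(str, np.random.default_rng(int(seeds[0])).choice(ids, size=config.module_size, replace=False))
    )
    network = simulate_network(config, annotation, module_genes, seed=int(seeds[1]))
    module_mask = np.isin(np.array(ids), np.array(module_genes))
    rates = gene_rate_profiles(config, module_mask, seed=int(seeds[0]))
    discovery = simulate_cohort(config, annotation, module_genes, "D", seed=int(seeds[2]), rates=rates)
    validation = simulate_cohort(config, annotation, module_genes, "V", seed=int(seeds[3]), rates=rates)
    return SimBundle(
        config=config,
        annotation=annotation,
        network=network,
        module_genes=list(module_genes),
        discovery=discovery,
        validation=validation,
        gain_rates=pd.Series(rates[0], index=ids, name="gain_rate"),
        loss_rates=pd.Series(rates[1], index=ids, name="loss_rate"),
    )


def simulate_expression(
    module_genes,
    scores: pd.Series,
    n_background: int = 20,
    effect: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x samples expression matrix with a linear survival signal.

    Module genes track the (standardized) mutation score with slope
    ``effect`` plus Gaussian noise; background genes are pure noise.  This
    is the minimal structure the risk-score flow needs, not a realistic
    expression model.
    """
    rng = np.random.default_rng(seed)
    z = (scores - scores.mean()) / (scores.std() if scores.std() > 0 else 1.0)
    rows = {}
    for g in module_genes:
        rows[g] = effect * z.to_numpy() + rng.normal(0, noise_sd, size=len(z))
    for b in range(n_background):
        rows[f"BG{b + 1:03d}"] = rng.normal(0, noise_sd, size=len(z))
    return pd.DataFrame(rows, index=scores.index).T


# ---------------------------------------------------------------------------
# file output


def write_bundle(bundle: SimBundle, out_dir) -> None:
    """Write the bundle as plain-text pipeline inputs plus truth.json.

    Files: annotation.bed, network.tsv, {discovery,validation}.seg.tsv,
    {discovery,validation}.surv.tsv and truth.json (planted module,
    configured rates and effect).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "annotation.bed", "w") as fh:
        for g in bundle.annotation:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    with open(out / "network.tsv", "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in bundle.network.edges()):
            fh.write(f"{u}\t{v}\n")
    for name, cohort in (("discovery", bundle.discovery), ("validation", bundle.validation)):
        seg = pd.DataFrame(
            [
                (s.sample_id, s.chrom, s.start, s.end, s.n_probes, s.state)
                for s in cohort.segments
            ],
            columns=["sample", "chrom", "start", "end", "n_probes", "state"],
        )
        seg.to_csv(out / f"{name}.seg.tsv", sep="\t", index=False)
        cohort.survival.to_csv(out / f"{name}.surv.tsv", sep="\t", index_label="sample")
    truth = {
        "module_genes": bundle.module_genes,
        "config": dataclasses.asdict(bundle.config),
    }
    if bundle.gain_rates is not None:
        truth["gain_rates"] = {g: round(float(v), 10) for g, v in bundle.gain_rates.items()}
        truth["loss_rates"] = {g: round(float(v), 10) for g, v in bundle.loss_rates.items()}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
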