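"""Synthetic datasets with known gain/loss ground truth.

The generator emulates the structure of a phylotranscriptomic survey: a
binary gene (presence/absence) evolves along a rooted tree as a two-state
continuous-time Markov chain (gain events at ``gain_rate`` while absent,
loss events at ``loss_rate`` while present, per unit branch length); each
truly present gene is then *observed* only with probability
``detection_prob`` per sample, emulating the incompleteness of de novo
assembled transcriptomes; observed hits get bitscores drawn above the
calling threshold, and sub-threshold spurious hits can be sprinkled in to
exercise the calling edge. Every stage is a pure function of its inputs and
a seed, and the ground truth (per-branch events, true tip states, dropout
flags) is recorded so detector power and false-discovery behaviour can be
scored exactly.

Default rates (loss 0.1, gain 0.01 per unit length) make losses common and
regains rare — the Dollo-like asymmetry that motivates reading skewed hit
distributions as losses. The default detection probability of 0.9 is a
deliberately pessimistic stand-in for per-gene transcriptome completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import FormatError, ParameterError
from .hits import DEFAULT_THRESHOLD
from .trees import (SplitResult, best_splits, cut_levels, leaf_labels,
                    parse_newick, to_newick)

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BitscoreModel:
    """Bitscore emission for observed hits: true hits score
    ``threshold + offset + Exponential(scale)`` bits; spurious hits arrive
    as Poisson(``spurious_rate``) per sample-gene, scored uniformly below
    the threshold (so they never flip a call but populate the sub-threshold
    score range)."""

    offset: float = 1.0
    scale: float = 20.0
    spurious_rate: float = 0.1

    def __post_init__(self):
        if self.offset < 0 or self.scale <= 0 or self.spurious_rate < 0:
            raise ParameterError("invalid bitscore model parameters")


@dataclass(frozen=True)
class SimConfig:
    """Full study-condition description for one synthetic dataset."""

    n_taxa: int = 32
    tree_model: str = "yule"            # "yule" or "balanced"
    gain_rate: float = 0.01             # per unit branch length, while absent
    loss_rate: float = 0.1              # per unit branch length, while present
    root_state: int | str = 1           # 0, 1 or "stationary"
    detection_prob: float = 0.9         # per present gene per sample
    n_genes: int = 20
    threshold: float = DEFAULT_THRESHOLD
    bitscore: BitscoreModel = field(default_factory=BitscoreModel)
    n_clades: int = 5                   # clade map from the shallowest cuts
    planted_losses: tuple[tuple[int, str], ...] = ()  # (gene index, node_id)
    lipid_marker_gene: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ParameterError("n_taxa must be >= 2")
        if self.tree_model not in ("yule", "balanced"):
            raise ParameterError(f"unknown tree model {self.tree_model!r}")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ParameterError("rates must be >= 0")
        if not 0 <= self.detection_prob <= 1:
            raise ParameterError("detection_prob must be in [0, 1]")
        if self.n_genes < 0:
            raise ParameterError("n_genes must be >= 0")
        if self.root_state not in (0, 1, "stationary"):
            raise ParameterError("root_state must be 0, 1 or 'stationary'")


@dataclass(frozen=True)
class TraitEvent:
    """One state flip on the branch leading to ``node_id``, at fractional
    ``position`` along that branch."""

    node_id: str
    kind: str        # "gain" or "loss"
    position: float  # in (0, 1)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one gene: the replayable event list, the true tip
    states it implies, and (after dropout) which present copies were
    observed. ``dropped`` is present-but-unobserved, so dropped implies
    truly present."""

    gene_id: str
    root_state: int
    tip_states: dict[str, int]
    events: tuple[TraitEvent, ...]
    observed: dict[str, bool] | None = None

    @property
    def has_events(self) -> bool:
        return len(self.events) > 0

    def dropped(self) -> dict[str, bool]:
        if self.observed is None:
            raise ParameterError("dropout has not been applied yet")
        return {s: bool(state) and not self.observed[s]
                for s, state in self.tip_states.items()}


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(n_taxa: int, tree_model: str = "yule",
                  seed: int = 0) -> dendropy.Tree:
    """Simulate a rooted tree with ``n_taxa`` leaves labeled t1..tn.

    ``balanced``: a fully balanced binary tree (n_taxa must be a power of
    two) with unit branch lengths. ``yule``: a pure-birth tree (rate 1);
    branch lengths are in units of expected birth intervals. Deterministic
    given the seed.
    """
    if n_taxa < 2:
        raise ParameterError("n_taxa must be >= 2")
    if tree_model == "balanced":
        if n_taxa & (n_taxa - 1):
            raise ParameterError("balanced trees require n_taxa a power of 2")
        labels = [f"t{i + 1}" for i in range(n_taxa)]

        def build(block: list[str]) -> str:
            if len(block) == 1:
                return f"{block[0]}:1.0"
            mid = len(block) // 2
            return f"({build(block[:mid])},{build(block[mid:])}):1.0"

        mid = n_taxa // 2
        newick = f"({build(labels[:mid])},{build(labels[mid:])});"
        return parse_newick(newick)
    if tree_model != "yule":
        raise ParameterError(f"unknown tree model {tree_model!r}")

    rng = np.random.default_rng(seed)
    # grow tips under a pure-birth process; record each node's birth time
    next_id = [0]

    def fresh() -> dict:
        node = {"id": next_id[0], "birth": 0.0, "children": []}
        next_id[0] += 1
        return node

    root = fresh()
    tips = []
    for _ in range(2):
        child = fresh()
        root["children"].append(child)
        tips.append(child)
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / len(tips))
        parent = tips.pop(int(rng.integers(len(tips))))
        parent["birth_set"] = True
        parent["split"] = t
        for _ in range(2):
            child = fresh()
            child["birth"] = t
            parent["children"].append(child)
            tips.append(child)
    t_end = t + rng.exponential(1.0 / n_taxa)

    label_counter = [0]

    def emit(node: dict) -> str:
        if not node["children"]:
            label_counter[0] += 1
            length = t_end - node["birth"]
            return f"t{label_counter[0]}:{length:.6f}"
        end = node.get("split", t_end)
        inner = ",".join(emit(c) for c in node["children"])
        length = end - node["birth"]
        return f"({inner}):{length:.6f}"

    newick = emit(root).rsplit(":", 1)[0] + ";"
    return parse_newick(newick)


def clade_node_of_size(tree: dendropy.Tree, size: int) -> str:
    """node_id of the first (preorder) non-root clade with exactly ``size``
    leaves — convenient for planting a loss on a clade of known size."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if sum(1 for _ in node.leaf_iter()) == size:
            return node.node_id
    raise ParameterError(f"no clade of size {size} in tree")


# ---------------------------------------------------------------------------
# trait simulation

def _branch_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 1.0


def simulate_trait(tree: dendropy.Tree, gain_rate: float, loss_rate: float,
                   root_state: int | str = 1, seed: int | None = 0,
                   rng: np.random.Generator | None = None,
                   gene_id: str = "g1") -> SimTruth:
    """Evolve one binary trait along the tree as a two-state CTMC.

    While the gene is present, loss events arrive at ``loss_rate`` per unit
    branch length; while absent, gains arrive at ``gain_rate``. Events are
    drawn branch by branch in preorder (Gillespie within each branch); tip
    states are the replay of the event list from the root state.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ParameterError("rates must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if root_state == "stationary":
        total = gain_rate + loss_rate
        if total == 0:
            raise ParameterError("stationary root state needs a nonzero rate")
        state0 = int(rng.random() < gain_rate / total)
    else:
        state0 = int(root_state)

    events: list[TraitEvent] = []
    tip_states: dict[str, int] = {}
    state_at: dict[int, int] = {id(tree.seed_node): state0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state = state_at[id(node.parent_node)]
        length = _branch_length(node)
        pos = 0.0
        while True:
            rate = loss_rate if state else gain_rate
            if rate == 0:
                break
            step = rng.exponential(1.0 / rate)
            if pos + step >= length:
                break
            pos += step
            kind = "loss" if state else "gain"
            state = 1 - state
            events.append(TraitEvent(node.node_id, kind, pos / length))
        state_at[id(node)] = state
        if node.is_leaf():
            tip_states[node.taxon.label] = state
    return SimTruth(gene_id, state0, tip_states, tuple(events))


def planted_loss_trait(tree: dendropy.Tree, node_id: str,
                       gene_id: str = "g1",
                       position: float = 0.5) -> SimTruth:
    """Deterministic truth: the gene is present from the root and lost once,
    on the branch leading to ``node_id`` — the canonical clade-specific loss
    scenario."""
    target = None
    for node in tree.preorder_node_iter():
        if getattr(node, "node_id", None) == node_id:
            target = node
            break
    if target is None or target.parent_node is None:
        raise ParameterError(f"no non-root node with id {node_id!r}")
    lost = {l.taxon.label for l in target.leaf_iter()}
    tip_states = {label: 0 if label in lost else 1
                  for label in leaf_labels(tree)}
    return SimTruth(gene_id, 1, tip_states,
                    (TraitEvent(node_id, "loss", position),))


# ---------------------------------------------------------------------------
# observation model

def apply_dropout(truths: list[SimTruth], detection_prob: float,
                  bitscore_model: BitscoreModel | None = None,
                  threshold: float = DEFAULT_THRESHOLD,
                  seed: int | None = 0,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[pd.DataFrame, list[SimTruth]]:
    """Turn true tip states into an observed hit table.

    Each truly present (sample, gene) emits one supra-threshold hit with
    probability ``detection_prob``; truly absent genes emit none. Spurious
    sub-threshold hits are added per the bitscore model. Returns the hit
    records (sample_id, hmm_id, transcript_id, bitscore) plus copies of the
    truths with per-sample ``observed`` flags filled in.
    """
    if not 0 <= detection_prob <= 1:
        raise ParameterError("detection_prob must be in [0, 1]")
    model = bitscore_model or BitscoreModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    out_truths = []
    for truth in truths:
        observed = {}
        for sample in sorted(truth.tip_states):
            present = bool(truth.tip_states[sample])
            detected = False
            if present and rng.random() < detection_prob:
                detected = True
                score = threshold + model.offset + rng.exponential(model.scale)
                rows.append((sample, truth.gene_id,
                             f"{sample}|{truth.gene_id}|1", round(score, 4)))
            if model.spurious_rate > 0:
                for j in range(rng.poisson(model.spurious_rate)):
                    score = rng.uniform(0.0, threshold)
                    rows.append((sample, truth.gene_id,
                                 f"{sample}|{truth.gene_id}|noise{j + 1}",
                                 round(score, 4)))
            observed[sample] = detected
        out_truths.append(replace(truth, observed=observed))
    hits = pd.DataFrame(rows, columns=["sample_id", "hmm_id", "transcript_id",
                                       "bitscore"])
    return hits, out_truths


# ---------------------------------------------------------------------------
# whole datasets

def _clade_map_from_tree(tree: dendropy.Tree, n_clades: int):
    """Label samples by the shallowest tree cut with >= n_clades clusters
    (or the deepest available cut if the tree is too small)."""
    from .hits import CladeMap
    partitions = cut_levels(tree)
    chosen = partitions[-1]
    for part in partitions:
        if part.n_clusters >= n_clades:
            chosen = part
            break
    mapping = {}
    order = []
    for i, cluster in enumerate(chosen.clusters, start=1):
        label = f"clade_{i}"
        order.append(label)
        for sample in sorted(cluster.samples):
            mapping[sample] = label
    return CladeMap(mapping, tuple(order))


def _simulate_lipids(truth: SimTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Lipid AUC table tied to a marker gene's true tip states: every sample
    gets PC species; samples truly carrying the marker also get DGTS at a
    total abundance exceeding PC (ratio lognormal around 3), emulating
    marker-positive strains having more DGTS than PC."""
    rows = []
    for sample in sorted(truth.tip_states):
        pc_species = np.exp(rng.normal(13.0, 0.5, size=3))
        for i, auc in enumerate(pc_species, start=1):
            rows.append((sample, "PC", f"PC_{i}", round(float(auc), 2)))
        if truth.tip_states[sample]:
            ratio = float(np.exp(rng.normal(np.log(3.0), 0.4)))
            dgts_total = float(pc_species.sum()) * ratio
            shares = rng.dirichlet(np.ones(3))
            for i, share in enumerate(shares, start=1):
                rows.append((sample, "DGTS", f"DGTS_{i}",
                             round(dgts_total * float(share), 2)))
    return pd.DataFrame(rows, columns=["sample_id", "lipid_class",
                                       "species_id", "abundance"])


def _truth_payload(config: SimConfig, truths: list[SimTruth]) -> dict:
    return {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": config.seed,
        "config": {k: (asdict(v) if isinstance(v, BitscoreModel) else v)
                   for k, v in asdict(config).items()},
        "genes": [
            {
                "gene_id": t.gene_id,
                "root_state": t.root_state,
                "events": [asdict(e) for e in t.events],
                "tip_states": t.tip_states,
                "observed": t.observed,
            }
            for t in truths
        ],
    }


def generate_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate a complete, mutually consistent dataset and write it out.

    Produces ``tree.nwk``, ``hits.tsv``, ``clades.tsv``, ``truth.json`` and,
    when a lipid marker gene is configured, ``lipids.tsv`` — exactly the
    formats the analysis stages consume. Byte-identical across runs with the
    same config (seeds are recorded in the file headers, no timestamps).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {outdir}: {exc}") from exc
    dataset = simulate_dataset(config)
    header = (f"# skewscan {_version} simulate seed={config.seed} "
              f"n_taxa={config.n_taxa} n_genes={config.n_genes} "
              f"detection_prob={config.detection_prob}")
    paths = {}

    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(to_newick(dataset["tree"]), encoding="utf-8")

    paths["hits"] = outdir / "hits.tsv"
    with open(paths["hits"], "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        dataset["hits"].to_csv(fh, sep="\t", index=False, lineterminator="\n")

    paths["clades"] = outdir / "clades.tsv"
    with open(paths["clades"], "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        fh.write("sample_id\tclade\n")
        for sample, label in dataset["clades"].mapping.items():
            fh.write(f"{sample}\t{label}\n")

    paths["truth"] = outdir / "truth.json"
    payload = _truth_payload(config, dataset["truths"])
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True)
                              + "\n", encoding="utf-8")

    if dataset["lipids"] is not None:
        paths["lipids"] = outdir / "lipids.tsv"
        with open(paths["lipids"], "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            dataset["lipids"].to_csv(fh, sep="\t", index=False,
                                     lineterminator="\n")
    return paths


def simulate_dataset(config: SimConfig) -> dict:
    """In-memory version of ``generate_dataset``: returns the tree, the hit
    records, the clade map, the filled-in truths and the optional lipid
    table, all keyed to ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    tree = simulate_tree(config.n_taxa, config.tree_model,
                         seed=seeds[0].generate_state(1)[0])
    planted = dict(config.planted_losses)
    trait_rng = np.random.default_rng(seeds[1])
    truths = []
    for i in range(config.n_genes):
        gene_id = f"g{i + 1}"
        if i in planted:
            truths.append(planted_loss_trait(tree, planted[i], gene_id))
        else:
            truths.append(simulate_trait(tree, config.gain_rate,
                                         config.loss_rate, config.root_state,
                                         rng=trait_rng, gene_id=gene_id))
    hits, truths = apply_dropout(truths, config.detection_prob,
                                 config.bitscore, config.threshold,
                                 rng=np.random.default_rng(seeds[2]))
    clades = _clade_map_from_tree(tree, config.n_clades)
    lipids = None
    if config.lipid_marker_gene is not None:
        marker = truths[config.lipid_marker_gene]
        lipids = _simulate_lipids(marker, np.random.default_rng(seeds[3]))
    return {"tree": tree, "hits": hits, "clades": clades, "truths": truths,
            "lipids": lipids}


def load_truths(path) -> list[SimTruth]:
    """Reload a truth.json written by ``generate_dataset``."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != TRUTH_SCHEMA_VERSION:
        raise FormatError(f"unsupported truth schema: "
                          f"{payload.get('schema_version')!r}")
    return [
        SimTruth(g["gene_id"], g["root_state"], dict(g["tip_states"]),
                 tuple(TraitEvent(**e) for e in g["events"]),
                 dict(g["observed"]) if g["observed"] is not None else None)
        for g in payload["genes"]
    ]


# ---------------------------------------------------------------------------
# scoring detectors against the truth

@dataclass(frozen=True)
class DetectionScore:
    """Detector performance against simulation ground truth.

    power: fraction of event-carrying genes whose best split is significant
    and sits on a true event branch. false_discovery_rate: fraction of
    event-free genes whose best split is nonetheless significant.
    branch_accuracy: fraction of event-carrying genes whose best split sits
    on a true event branch, significant or not. NaN where the denominator
    is empty.
    """

    power: float
    false_discovery_rate: float
    branch_accuracy: float
    n_event_genes: int
    n_null_genes: int


def evaluate_detection(tree: dendropy.Tree, scan_results: list[SplitResult],
                       truths: list[SimTruth],
                       alpha: float = 1e-3) -> DetectionScore:
    """Score a branch scan against the simulator's ground truth.

    A true event on the branch to node v affects exactly the clade below v;
    a best split "matches" when its cluster's leaf set equals such a clade.
    """
    if not scan_results:
        raise ParameterError("empty scan results")
    best = best_splits(scan_results)
    genes_scanned = set(best)
    genes_truth = {t.gene_id for t in truths}
    if genes_scanned != genes_truth:
        raise FormatError(
            f"gene sets differ; only in scan: {sorted(genes_scanned - genes_truth)}; "
            f"only in truth: {sorted(genes_truth - genes_scanned)}")

    clade_of: dict[str, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        clade_of[node.node_id] = frozenset(
            l.taxon.label for l in node.leaf_iter())

    n_power = n_match = n_event = n_null = n_false = 0
    for truth in truths:
        b = best[truth.gene_id]
        if truth.has_events:
            n_event += 1
            true_clades = {clade_of[e.node_id] for e in truth.events}
            matches = clade_of[b.node_id] in true_clades
            n_match += matches
            n_power += matches and b.p_value < alpha
        else:
            n_null += 1
            n_false += b.p_value < alpha
    nan = float("nan")
    return DetectionScore(
        power=n_power / n_event if n_event else nan,
        false_discovery_rate=n_false / n_null if n_null else nan,
        branch_accuracy=n_match / n_event if n_event else nan,
        n_event_genes=n_event,
        n_null_genes=n_null,
    )
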