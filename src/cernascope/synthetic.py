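"""Seeded synthetic datasets with the structure the ceRNA analysis assumes.

The generator emulates a small two-group microarray study (default 4 case vs
4 control arrays measuring mRNAs and lncRNAs on the log2 scale) and plants
every signal the downstream pipeline is designed to detect:

* differentially expressed genes, shifted by ``planted_log2fc`` in the case
  group (half up, half down);
* near-perfect lncRNA-mRNA co-expression, planted by profile sharing — a
  paired mRNA's profile is its partner lncRNA's profile plus noise of sd
  ``coexpr_noise_sd``, which guarantees the Pearson r > 0.97 gate is reachable
  with only eight samples;
* ceRNA triples: each planted (lncRNA, mRNA) pair is wired through one or
  more miRNAs via lncRNA->miRNA and miRNA->mRNA interaction rows, with one
  designated hub lncRNA mediated by ``hub_lnc_mirna_fanout`` distinct miRNAs;
* a dense planted clique in the PPI edge list (scores >= 0.9) over a subset
  of the planted DE mRNAs, plus sparse random background edges;
* one gene set enriched for planted DE mRNAs among random background sets.

miRNA expression values are deliberately not generated: the assay design only
measures lncRNAs and mRNAs, and miRNAs enter the analysis solely through the
interaction tables. The matching ground truth is returned (and written) so
recovery tests never need to reach into generator internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import sha256_file, write_json, write_tsv
from .matrix import ExpressionMatrix, write_expression


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic two-group array experiment."""

    n_case: int = 4
    n_control: int = 4
    n_mrna: int = 2000
    n_lncrna: int = 500
    n_mirna: int = 300
    n_de_mrna: int = 60
    n_de_lncrna: int = 30
    planted_log2fc: float = 2.0      # case-group shift, log2 units
    noise_sd: float = 0.25           # per-array noise, log2 units
    coexpr_noise_sd: float = 0.02    # profile-sharing noise, log2 units
    n_triples: int = 40
    hub_lnc_mirna_fanout: int = 30
    background_pair_rate: float = 0.002
    ppi_clique_size: int = 22        # planted clique (>= 6) over DE mRNAs
    seed: int = 0

    # how many distinct mRNA partners the hub lncRNA is co-expressed with
    _HUB_MRNA_PARTNERS = 3

    def validate(self) -> None:
        counts = dict(n_case=self.n_case, n_control=self.n_control,
                      n_mrna=self.n_mrna, n_lncrna=self.n_lncrna,
                      n_mirna=self.n_mirna)
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0 (got {value})")
        for name, value in [("n_de_mrna", self.n_de_mrna),
                            ("n_de_lncrna", self.n_de_lncrna),
                            ("n_triples", self.n_triples),
                            ("hub_lnc_mirna_fanout", self.hub_lnc_mirna_fanout)]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {value})")
        if self.n_de_mrna > self.n_mrna:
            raise ConfigurationError("n_de_mrna exceeds n_mrna")
        if self.n_de_lncrna > self.n_lncrna:
            raise ConfigurationError("n_de_lncrna exceeds n_lncrna")
        if not 0.0 <= self.background_pair_rate <= 1.0:
            raise ConfigurationError("background_pair_rate must lie in [0, 1]")
        if self.coexpr_noise_sd >= self.noise_sd:
            raise ConfigurationError(
                "coexpr_noise_sd must be < noise_sd so planted pairs can pass "
                "the r > 0.97 gate")
        if self.n_triples > 0:
            if self.hub_lnc_mirna_fanout > self.n_triples:
                raise ConfigurationError(
                    "hub_lnc_mirna_fanout exceeds n_triples")
            if self.n_triples > self.n_mirna:
                raise ConfigurationError(
                    "n_triples exceeds n_mirna (one distinct miRNA per triple)")
            if self._n_pair_lncrnas() > self.n_de_lncrna:
                raise ConfigurationError(
                    f"triple wiring needs {self._n_pair_lncrnas()} DE lncRNAs "
                    f"but n_de_lncrna={self.n_de_lncrna}")
            if self._n_pair_mrnas() > self.n_de_mrna:
                raise ConfigurationError(
                    f"triple wiring needs {self._n_pair_mrnas()} DE mRNAs "
                    f"but n_de_mrna={self.n_de_mrna}")
        if self.n_de_mrna > 0:
            if self.ppi_clique_size < 6:
                raise ConfigurationError("ppi_clique_size must be >= 6")
            if self.ppi_clique_size > self.n_de_mrna:
                raise ConfigurationError(
                    "ppi_clique_size exceeds n_de_mrna (clique is planted over "
                    "DE mRNAs)")

    def _n_hub_mrnas(self) -> int:
        if self.n_triples == 0 or self.hub_lnc_mirna_fanout == 0:
            return 0
        return min(self._HUB_MRNA_PARTNERS, self.hub_lnc_mirna_fanout)

    def _n_extra_triples(self) -> int:
        return self.n_triples - self.hub_lnc_mirna_fanout if self.n_triples else 0

    def _n_pair_lncrnas(self) -> int:
        # hub (if any fanout) + one lncRNA per extra triple
        return (1 if self.hub_lnc_mirna_fanout else 0) + self._n_extra_triples()

    def _n_pair_mrnas(self) -> int:
        return self._n_hub_mrnas() + self._n_extra_triples()


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each synthetic dataset."""

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_triples: set[tuple[str, str, str]] = field(default_factory=set)
    hub_lncrna: str | None = None
    ppi_clique: set[str] = field(default_factory=set)
    enriched_set_name: str | None = None

    def validate(self, config: SimConfig) -> None:
        for l, m, g in self.planted_triples:
            if (l, g) not in self.planted_pairs:
                raise ValueError(f"triple ({l},{m},{g}) lacks its planted pair")
        if self.hub_lncrna is not None:
            n = sum(1 for t in self.planted_triples if t[0] == self.hub_lncrna)
            if n < config.hub_lnc_mirna_fanout:
                raise ValueError("hub lncRNA participates in too few triples")


@dataclass
class SyntheticDataset:
    """Everything :func:`generate_dataset` produces, ready for the pipeline."""

    matrix: ExpressionMatrix
    lnc_mir: pd.DataFrame      # source_id, target_id, source_type, target_type
    mir_mrna: pd.DataFrame
    ppi: pd.DataFrame          # gene_a, gene_b, combined_score
    gene_sets: dict[str, list[str]]
    truth: GroundTruth
    config: SimConfig


def _interaction_frame(rows: list[tuple[str, str]], source_type: str,
                       target_type: str) -> pd.DataFrame:
    rows = sorted(set(rows))
    return pd.DataFrame(
        {"source_id": [r[0] for r in rows],
         "target_id": [r[1] for r in rows],
         "source_type": source_type,
         "target_type": target_type})


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one synthetic study; identical config+seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mrna_ids = np.array([f"MRNA{i:05d}" for i in range(config.n_mrna)])
    lnc_ids = np.array([f"LNC{i:05d}" for i in range(config.n_lncrna)])
    mir_ids = np.array([f"MIR{i:04d}" for i in range(config.n_mirna)])
    gene_ids = np.concatenate([mrna_ids, lnc_ids])
    n_genes = len(gene_ids)
    sample_ids = ([f"case_{i + 1}" for i in range(config.n_case)]
                  + [f"control_{i + 1}" for i in range(config.n_control)])
    n_samples = len(sample_ids)
    case_cols = np.arange(config.n_case)

    # baseline log2 intensities in a plausible microarray range
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                            size=(n_genes, n_samples))

    # --- plant differential expression ---------------------------------------
    truth = GroundTruth()
    de_mrna = rng.choice(mrna_ids, size=config.n_de_mrna, replace=False)
    de_lnc = rng.choice(lnc_ids, size=config.n_de_lncrna, replace=False)
    row_of = {g: i for i, g in enumerate(gene_ids)}
    direction: dict[str, int] = {}
    for ids in (de_mrna, de_lnc):
        for j, g in enumerate(ids):
            direction[g] = +1 if j < (len(ids) + 1) // 2 else -1
    for g, sign in direction.items():
        values[row_of[g], case_cols] += sign * config.planted_log2fc

    # --- plant co-expression pairs and ceRNA triples -------------------------
    pair_lncs = list(de_lnc[:config._n_pair_lncrnas()])
    pair_mrnas = list(de_mrna[:config._n_pair_mrnas()])
    lnc_mir_rows: list[tuple[str, str]] = []
    mir_mrna_rows: list[tuple[str, str]] = []
    if config.n_triples > 0 and pair_lncs:
        triple_mirs = rng.choice(mir_ids, size=config.n_triples, replace=False)
        hub = pair_lncs[0] if config.hub_lnc_mirna_fanout else None
        truth.hub_lncrna = hub
        n_hub_m = config._n_hub_mrnas()
        hub_partners = pair_mrnas[:n_hub_m]
        extra_lncs = pair_lncs[1 if hub else 0:]
        extra_mrnas = pair_mrnas[n_hub_m:]

        pairs: list[tuple[str, str]] = []
        if hub is not None:
            pairs += [(hub, g) for g in hub_partners]
            for i in range(config.hub_lnc_mirna_fanout):
                m = triple_mirs[i]
                g = hub_partners[i % n_hub_m]
                truth.planted_triples.add((hub, m, g))
                lnc_mir_rows.append((hub, m))
                mir_mrna_rows.append((m, g))
        for j, (l, g) in enumerate(zip(extra_lncs, extra_mrnas)):
            m = triple_mirs[config.hub_lnc_mirna_fanout + j]
            pairs.append((l, g))
            truth.planted_triples.add((l, m, g))
            lnc_mir_rows.append((l, m))
            mir_mrna_rows.append((m, g))
        truth.planted_pairs = set(pairs)

        # profile sharing: paired mRNA = partner lncRNA profile (re-centred on
        # the mRNA's own baseline) + tiny noise; inherits the lncRNA's DE shift
        for l, g in pairs:
            li, gi = row_of[l], row_of[g]
            values[gi] = (values[li] - baseline[li] + baseline[gi]
                          + rng.normal(0.0, config.coexpr_noise_sd, n_samples))
            direction[g] = direction[l]

    truth.de_genes_up = {g for g, s in direction.items() if s > 0}
    truth.de_genes_down = {g for g, s in direction.items() if s < 0}

    # --- background interaction rows ------------------------------------------
    if config.background_pair_rate > 0:
        mask = rng.random((config.n_lncrna, config.n_mirna)) < config.background_pair_rate
        li, mi = np.nonzero(mask)
        lnc_mir_rows += list(zip(lnc_ids[li], mir_ids[mi]))
        mask = rng.random((config.n_mirna, config.n_mrna)) < config.background_pair_rate
        mi, gi = np.nonzero(mask)
        mir_mrna_rows += list(zip(mir_ids[mi], mrna_ids[gi]))

    lnc_mir = _interaction_frame(lnc_mir_rows, "lncRNA", "miRNA")
    mir_mrna = _interaction_frame(mir_mrna_rows, "miRNA", "mRNA")

    # --- PPI edge list: one dense clique over DE mRNAs + random background ----
    ppi_rows: list[tuple[str, str, float]] = []
    if config.n_de_mrna > 0:
        clique = pair_mrnas + [g for g in de_mrna if g not in set(pair_mrnas)]
        clique = clique[:config.ppi_clique_size]
        truth.ppi_clique = set(clique)
        for i in range(len(clique)):
            for j in range(i + 1, len(clique)):
                ppi_rows.append((clique[i], clique[j],
                                 float(rng.uniform(0.9, 1.0))))
    n_random_edges = max(1, config.n_mrna // 20)
    ra = rng.choice(mrna_ids, size=n_random_edges)
    rb = rng.choice(mrna_ids, size=n_random_edges)
    scores = rng.uniform(0.4, 0.9, size=n_random_edges)
    clique_set = truth.ppi_clique
    for a, b, s in zip(ra, rb, scores):
        if a != b and not (a in clique_set and b in clique_set):
            ppi_rows.append((a, b, float(s)))
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "combined_score"])
    ppi = ppi.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    # --- gene sets: one planted DE-enriched set + random background sets ------
    gene_sets: dict[str, list[str]] = {}
    if config.n_de_mrna > 0:
        n_sig = min(30, config.n_de_mrna)
        non_de = [g for g in mrna_ids if g not in direction]
        members = (list(de_mrna[:n_sig])
                   + list(rng.choice(non_de, size=min(20, len(non_de)),
                                     replace=False)))
        gene_sets["PLANTED_DE_SET"] = sorted(members)
        truth.enriched_set_name = "PLANTED_DE_SET"
    for i in range(19):
        size = int(rng.integers(20, 101))
        members = rng.choice(mrna_ids, size=size, replace=False)
        gene_sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(members)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        biotypes=pd.Series(["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
                           index=gene_ids),
        groups=pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                         index=sample_ids),
    )
    truth.validate(config)
    return SyntheticDataset(matrix, lnc_mir, mir_mrna, ppi, gene_sets, truth, config)


# --- persistence --------------------------------------------------------------

FILE_NAMES = {
    "matrix": "expression.tsv",
    "samples": "samples.tsv",
    "lnc_mir": "lncrna_mirna.tsv",
    "mir_mrna": "mirna_mrna.tsv",
    "ppi": "ppi.tsv",
    "gene_sets": "gene_sets.gmt",
    "ground_truth": "ground_truth.tsv",
}


def _truth_frame(truth: GroundTruth) -> pd.DataFrame:
    rows: list[tuple[str, str, str, str]] = []
    for g in sorted(truth.de_genes_up):
        rows.append(("de_up", g, "", ""))
    for g in sorted(truth.de_genes_down):
        rows.append(("de_down", g, "", ""))
    for l, g in sorted(truth.planted_pairs):
        rows.append(("pair", l, g, ""))
    for l, m, g in sorted(truth.planted_triples):
        rows.append(("triple", l, m, g))
    if truth.hub_lncrna:
        rows.append(("hub_lncrna", truth.hub_lncrna, "", ""))
    for g in sorted(truth.ppi_clique):
        rows.append(("ppi_clique", g, "", ""))
    if truth.enriched_set_name:
        rows.append(("enriched_set", truth.enriched_set_name, "", ""))
    return pd.DataFrame(rows, columns=["kind", "id1", "id2", "id3"])


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    t = GroundTruth()
    for kind, a, b, c in df.itertuples(index=False):
        if kind == "de_up":
            t.de_genes_up.add(a)
        elif kind == "de_down":
            t.de_genes_down.add(a)
        elif kind == "pair":
            t.planted_pairs.add((a, b))
        elif kind == "triple":
            t.planted_triples.add((a, b, c))
        elif kind == "hub_lncrna":
            t.hub_lncrna = a
        elif kind == "ppi_clique":
            t.ppi_clique.add(a)
        elif kind == "enriched_set":
            t.enriched_set_name = a
        else:
            raise ValueError(f"unknown ground-truth row kind: {kind}")
    return t


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write all dataset files plus a JSON manifest; returns the manifest."""
    from .enrichment import write_gmt  # local import to avoid cycles

    if not str(out_dir):
        raise ValueError("out_dir must be a non-empty path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_expression(dataset.matrix, out / FILE_NAMES["matrix"],
                     out / FILE_NAMES["samples"])
    write_tsv(dataset.lnc_mir, out / FILE_NAMES["lnc_mir"])
    write_tsv(dataset.mir_mrna, out / FILE_NAMES["mir_mrna"])
    write_tsv(dataset.ppi, out / FILE_NAMES["ppi"])
    write_gmt(dataset.gene_sets, out / FILE_NAMES["gene_sets"])
    write_tsv(_truth_frame(dataset.truth), out / FILE_NAMES["ground_truth"])

    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "seed": dataset.config.seed,
        "files": {name: sha256_file(out / fname)
                  for name, fname in FILE_NAMES.items()},
        "notes": ("distributional choices (uniform log2 baselines in [6,12], "
                  "gaussian array noise) are stand-ins; the generator plants "
                  "structure, it does not model a specific array platform"),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
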