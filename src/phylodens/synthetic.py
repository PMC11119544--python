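"""Synthetic trees, species effects, and site-species trait tables.

The generator reproduces the statistical structure that the analysis
assumes: a pure-birth ultrametric phylogeny; species-level effects with a
lambda-scaled Brownian phylogenetic component plus an independent species
component; several site records per species with residual noise; and site
covariates with specified linear effects (including zero-effect decoys).

Default parameters emulate the global wood-density study conditions:
mean density ~0.57 g/cm3, pooled SD ~0.20, and a variance split of roughly
84% phylogeny / 8% species / 1% environment / 7% residual.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .treekit import PhyloTree, PhyloCovariance, build_vcv, lambda_transform, read_newick

__all__ = ["CladeSpec", "SimConfig", "SimResult", "simulate_tree",
           "simulate_species_effects", "simulate_table"]

DEFAULT_BETA = {
    "mat": 0.001,
    "map": -1e-5,
    "clay": -0.0002,
    "ndvi": -0.01,
    "soc": 0.0,     # decoy: no effect
    "slope": 0.0,   # decoy
    "aspect": 0.0,  # decoy
}

DEFAULT_RANGES = {
    "mat": (-15.0, 30.0),
    "map": (0.0, 4500.0),
    "clay": (5.0, 60.0),
    "soc": (5.0, 80.0),
    "ndvi": (0.05, 0.95),
    "slope": (0.0, 35.0),
    "aspect": (0.0, 360.0),
}


@dataclass(frozen=True)
class CladeSpec:
    """A clade with its own number of species and true lambda."""

    name: str
    n_species: int
    lam: float


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Variances are on the trait (g/cm3 squared) scale.  ``clades``, when
    given, replaces ``n_species``/``lam`` by per-clade settings; clade
    subtrees are joined at a common root with short stems so cross-clade
    phylogenetic covariance is zero.
    """

    n_species: int = 300
    birth_rate: float = 1.0
    lam: float = 1.0
    sigma2_p: float = 0.0337
    sigma2_s: float = 0.0031
    sigma2_e: float = 0.0029
    intercept: float = 0.60
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sites_per_species: int = 3
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    clades: list[CladeSpec] | None = None
    ensure_positive: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.clades is None and self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        for name in ("sigma2_p", "sigma2_s", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sites_per_species < 1:
            raise ValueError("sites_per_species must be >= 1")


@dataclass
class SimResult:
    tree: PhyloTree
    table: pd.DataFrame
    truth: dict

    def write(self, tree_path, table_path, truth_path) -> None:
        from .treekit import write_newick

        with open(tree_path, "w") as fh:
            fh.write(write_newick(self.tree) + "\n")
        self.table.to_csv(table_path, index=False, float_format="%.10g")
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(type(x).__name__)


def _yule_newick(n_species: int, birth_rate: float, rng: np.random.Generator,
                 label_offset: int = 0) -> str:
    """Forward pure-birth simulation; returns an ultrametric Newick string."""
    # each active lineage: [children(list) or label, birth_time]
    nodes = []

    def new_node(t):
        nodes.append({"children": None, "start": t, "end": None})
        return len(nodes) - 1

    t = 0.0
    root = new_node(0.0)
    nodes[root]["children"] = [new_node(0.0), new_node(0.0)]
    active = list(nodes[root]["children"])
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active[k]
        nodes[parent]["end"] = t
        nodes[parent]["children"] = [new_node(t), new_node(t)]
        active[k : k + 1] = nodes[parent]["children"]
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for idx in active:
        nodes[idx]["end"] = t

    labels = {}
    for i, idx in enumerate(sorted(active)):
        labels[idx] = f"sp{label_offset + i + 1:04d}"

    def fmt(idx):
        nd = nodes[idx]
        length = (nd["end"] if nd["end"] is not None else t) - nd["start"]
        if nd["children"] is None:
            return f"{labels[idx]}:{length!r}"
        inner = ",".join(fmt(c) for c in nd["children"])
        return f"({inner}):{length!r}"

    inner = ",".join(fmt(c) for c in nodes[root]["children"])
    return f"({inner});"


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with tips ``sp0001...``.

    Deterministic given ``seed``: the same call yields a byte-identical
    Newick string.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    return read_newick(_yule_newick(n_species, birth_rate, rng))


def _unit_correlation(tree: PhyloTree, lam: float) -> PhyloCovariance:
    C = build_vcv(tree)
    d = np.sqrt(np.diag(C.matrix))
    corr = C.matrix / np.outer(d, d)
    return lambda_transform(PhyloCovariance(C.labels, corr), lam)


def simulate_species_effects(tree: PhyloTree, lam: float, sigma2_p: float,
                             sigma2_s: float, seed: int = 0) -> pd.DataFrame:
    """Draw per-species phylogenetic (a) and independent (s) effects.

    a ~ MVN(0, sigma2_p * Lambda(lam)) with Lambda the unit-diagonal
    lambda-transformed correlation of the tree; s ~ iid N(0, sigma2_s).
    """
    rng = np.random.default_rng(seed)
    corr = _unit_correlation(tree, lam)
    n = len(corr.labels)
    if sigma2_p > 0:
        # eigh is robust to the semidefinite lam=1 case with near-zero modes
        w, V = np.linalg.eigh(corr.matrix)
        w = np.clip(w, 0.0, None)
        a = np.sqrt(sigma2_p) * (V * np.sqrt(w)) @ rng.standard_normal(n)
    else:
        a = np.zeros(n)
        rng.standard_normal(n)  # keep the stream layout stable
    s = np.sqrt(sigma2_s) * rng.standard_normal(n)
    return pd.DataFrame({"species": list(corr.labels), "a": a, "s": s})


def _join_clade_trees(specs: list[CladeSpec], birth_rate: float,
                      rng: np.random.Generator) -> tuple[PhyloTree, dict[str, str]]:
    """Simulate one subtree per clade, rescale to unit height, join at a root.

    Stems of length 0.05 keep the joined tree ultrametric while making
    cross-clade shared path length zero up to the (common) root.
    """
    parts = []
    clade_of: dict[str, str] = {}
    offset = 0
    for spec in specs:
        sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        nwk = _yule_newick(spec.n_species, birth_rate, sub_rng,
                           label_offset=offset)
        sub = read_newick(nwk)
        height = max(sub.depths().values())
        scaled = _scale_newick_lengths(nwk.rstrip(";"), 1.0 / height)
        parts.append(f"{scaled}:0.05")
        for lab in sub.tip_labels:
            clade_of[lab] = spec.name
        offset += spec.n_species
    tree = read_newick("(" + ",".join(parts) + ");")
    return tree, clade_of


def _scale_newick_lengths(nwk: str, factor: float) -> str:
    import re

    def repl(m):
        return ":" + repr(float(m.group(1)) * factor)

    return re.sub(r":([0-9eE+.\-]+)", repl, nwk)


def _binomial_label(i: int) -> str:
    """Deterministic binomial-style species name for tip index i."""
    letters = []
    k = i
    for _ in range(4):
        letters.append(chr(ord("a") + k % 26))
        k //= 26
    return "Simulatus_" + "".join(reversed(letters))


def _relabel_binomial(tree: PhyloTree) -> tuple[PhyloTree, dict[str, str]]:
    """Rename sp#### tips to binomial-style names (passes name filters)."""
    import re

    from .treekit import write_newick

    mapping = {lab: _binomial_label(int(lab[2:])) for lab in tree.tip_labels}
    nwk = re.sub(r"sp(\d{4,})", lambda m: _binomial_label(int(m.group(1))),
                 write_newick(tree))
    return read_newick(nwk), mapping


def simulate_table(config: SimConfig) -> SimResult:
    """Generate (tree, site-species table, truth record).

    Each row: y = intercept + beta.x + a_species + s_species + e.  The
    table schema matches the dataset module's input format (tips renamed
    to binomial-style names so the record filter accepts them); site
    coordinates are unique jittered points.  The truth record stores every
    latent value and parameter for recovery scoring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.clades:
        tree, clade_raw = _join_clade_trees(config.clades, config.birth_rate, rng)
        tree, mapping = _relabel_binomial(tree)
        clade_of = {mapping[k]: v for k, v in clade_raw.items()}
        effects = []
        for spec in config.clades:
            labs = [lab for lab in tree.tip_labels if clade_of[lab] == spec.name]
            sub = extract_for(tree, labs)
            eff = simulate_species_effects(
                sub, spec.lam, config.sigma2_p, config.sigma2_s,
                seed=int(rng.integers(2**31 - 1)),
            )
            effects.append(eff)
        eff = pd.concat(effects, ignore_index=True)
    else:
        tree = simulate_tree(config.n_species, config.birth_rate,
                             seed=int(rng.integers(2**31 - 1)))
        tree, _ = _relabel_binomial(tree)
        clade_of = None
        eff = simulate_species_effects(
            tree, config.lam, config.sigma2_p, config.sigma2_s,
            seed=int(rng.integers(2**31 - 1)),
        )

    species = list(eff["species"])
    a = dict(zip(eff["species"], eff["a"]))
    s = dict(zip(eff["species"], eff["s"]))

    rows = []
    used_coords: set[tuple[float, float]] = set()
    covars = list(config.covariate_ranges)
    m = config.sites_per_species
    for sp in species:
        for _ in range(m):
            while True:
                lat = round(float(rng.uniform(-60, 70)), 5)
                lon = round(float(rng.uniform(-180, 180)), 5)
                if (lat, lon) not in used_coords:
                    used_coords.add((lat, lon))
                    break
            x = {c: float(rng.uniform(*config.covariate_ranges[c])) for c in covars}
            fixed = config.intercept + sum(
                config.beta.get(c, 0.0) * x[c] for c in covars
            )
            e = float(rng.normal(0.0, np.sqrt(config.sigma2_e)))
            y = fixed + a[sp] + s[sp] + e
            if config.ensure_positive and config.sigma2_e > 0:
                # wood density is strictly positive; redraw the residual for
                # the rare far-tail row (see methods note)
                while y <= 0.01:
                    e = float(rng.normal(0.0, np.sqrt(config.sigma2_e)))
                    y = fixed + a[sp] + s[sp] + e
            row = {"species": sp, "latitude": lat, "longitude": lon,
                   "wood_density": y}
            row.update(x)
            row["_e"] = e
            if clade_of is not None:
                row["clade"] = clade_of[sp]
            rows.append(row)

    table = pd.DataFrame(rows)
    latent_e = table.pop("_e").to_numpy()

    truth = {
        "config": _config_dict(config),
        "species": species,
        "a": [a[sp] for sp in species],
        "s": [s[sp] for sp in species],
        "residuals": latent_e,
        "seed": config.seed,
    }
    return SimResult(tree=tree, table=table, truth=truth)


def extract_for(tree: PhyloTree, labels) -> PhyloTree:
    from .treekit import extract_subtree

    return extract_subtree(tree, labels)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if config.clades:
        d["clades"] = [asdict(c) for c in config.clades]
    return d
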