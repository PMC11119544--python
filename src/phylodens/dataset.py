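"""Site-species trait records: filtering, aggregation, classification.

Implements the record-level quality filters (coordinates, species-level
names, positive density, optional tree-species allowlist), site-species
averaging, species means, climate-zone and Whittaker-biome classification,
and the one-way ANOVA / LSD group comparison used for biome summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from shapely.geometry import Point, Polygon

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLUMNS",
    "NINE_BIOMES",
    "ValidationError",
    "BiomeConfig",
    "GroupComparison",
    "filter_records",
    "aggregate_site_species",
    "species_mean",
    "classify_climate_zone",
    "classify_climate_zones",
    "classify_biome",
    "classify_biomes",
    "compare_groups",
    "load_table",
]

REQUIRED_COLUMNS = ("species", "latitude", "longitude", "wood_density")
COVARIATE_COLUMNS = ("mat", "map", "clay", "soc", "ndvi", "slope", "aspect")

NINE_BIOMES = (
    "tundra",
    "boreal forest",
    "temperate seasonal forest",
    "temperate rain forest",
    "tropical rain forest",
    "tropical seasonal forest/savanna",
    "subtropical desert",
    "temperate grassland/desert",
    "woodland/shrubland",
)

#: epithets that mark a name as not identified to species level
_PLACEHOLDER_EPITHETS = {"sp", "sp.", "spp", "spp.", "indet", "indet.",
                         "cf", "cf.", "aff", "aff."}


class ValidationError(ValueError):
    """Input data violates a documented contract."""


def load_table(path) -> pd.DataFrame:
    """Read a delimited trait table (comma or tab inferred from suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# filtering


def _is_species_level(name) -> bool:
    if not isinstance(name, str):
        return False
    # tree tips conventionally use Genus_species; treat '_' as a separator
    tokens = name.replace("_", " ").strip().split()
    if len(tokens) < 2:
        return False
    epithet = tokens[1]
    if epithet.lower() in _PLACEHOLDER_EPITHETS:
        return False
    return epithet.replace("-", "").isalpha() and len(epithet) >= 2


def _valid_coordinates(lat, lon) -> bool:
    try:
        lat = float(lat)
        lon = float(lon)
    except (TypeError, ValueError):
        return False
    return (math.isfinite(lat) and math.isfinite(lon)
            and -90 <= lat <= 90 and -180 <= lon <= 180)


def filter_records(records: pd.DataFrame, allowlist=None):
    """Apply the record-level quality filters.

    Rules are applied in a fixed order and only the first failure is
    logged per record: (1) coordinates present and in range, (2) species
    name at species level or below, (3) wood density present and positive,
    (4) species in the tree-species allowlist when one is supplied.

    Returns ``(kept, rejection_log)`` where the log is a list of dicts with
    the record's positional index, species, and one reason.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValidationError(f"missing required column {col!r}")
    allow = set(allowlist) if allowlist is not None else None

    keep_mask = np.ones(len(records), dtype=bool)
    log: list[dict] = []
    for pos, (_, row) in enumerate(records.iterrows()):
        if not _valid_coordinates(row["latitude"], row["longitude"]):
            reason = "missing or invalid coordinates"
        elif not _is_species_level(row["species"]):
            reason = "name not at species level"
        elif not (pd.notna(row["wood_density"])
                  and math.isfinite(float(row["wood_density"]))
                  and float(row["wood_density"]) > 0):
            reason = "non-positive or missing wood density"
        elif allow is not None and row["species"] not in allow:
            reason = "not in tree-species allowlist"
        else:
            continue
        keep_mask[pos] = False
        log.append({"index": pos, "species": row["species"], "reason": reason})
    return records.loc[keep_mask].copy(), log


# ---------------------------------------------------------------------------
# aggregation

#: coordinate rounding that defines site identity (decimal places)
SITE_DECIMALS = 5


def aggregate_site_species(records: pd.DataFrame, atol: float = 1e-8) -> pd.DataFrame:
    """Average wood density per (site, species) cell.

    Site identity is the (latitude, longitude) pair rounded to
    ``SITE_DECIMALS`` places.  Covariates are site properties and must
    agree within a cell (tolerance ``atol`` for numeric columns), otherwise
    a :class:`ValidationError` names the offending cell.
    """
    df = records.copy()
    df["latitude"] = df["latitude"].astype(float).round(SITE_DECIMALS)
    df["longitude"] = df["longitude"].astype(float).round(SITE_DECIMALS)

    keys = ["latitude", "longitude", "species"]
    passthrough = [c for c in df.columns
                   if c not in keys and c != "wood_density"]
    out_rows = []
    for key, cell in df.groupby(keys, sort=True):
        row = dict(zip(keys, key))
        row["wood_density"] = float(cell["wood_density"].mean())
        row["n_records"] = int(len(cell))
        for c in passthrough:
            vals = cell[c]
            if pd.api.types.is_numeric_dtype(vals):
                lo, hi = float(vals.min()), float(vals.max())
                if hi - lo > atol:
                    raise ValidationError(
                        f"covariate {c!r} conflicts within site-species cell "
                        f"{key}: {lo} vs {hi}"
                    )
                row[c] = float(vals.iloc[0])
            else:
                if vals.nunique(dropna=False) > 1:
                    raise ValidationError(
                        f"column {c!r} conflicts within site-species cell {key}"
                    )
                row[c] = vals.iloc[0]
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    ordered = keys + ["wood_density", "n_records"] + passthrough
    return out[ordered]


def species_mean(table: pd.DataFrame, column: str = "wood_density") -> pd.Series:
    """Unweighted mean of a column across each species' site-species rows."""
    return table.groupby("species", sort=True)[column].mean()


# ---------------------------------------------------------------------------
# climate zones


def classify_climate_zone(mat_mean: float) -> str:
    """Zone from a species' mean MAT: >20 tropical, 20..5 temperate, <5 boreal.

    Both boundaries are closed on the temperate side (20 -> temperate,
    5 -> temperate).
    """
    if mat_mean is None or not math.isfinite(float(mat_mean)):
        raise ValidationError(f"non-finite MAT: {mat_mean!r}")
    mat_mean = float(mat_mean)
    if mat_mean > 20.0:
        return "tropical"
    if mat_mean >= 5.0:
        return "temperate"
    return "boreal"


def classify_climate_zones(table: pd.DataFrame) -> pd.Series:
    """Per-species zone from each species' average MAT over its sites."""
    mat_by_species = table.groupby("species")["mat"].mean()
    return mat_by_species.map(classify_climate_zone).rename("climate_zone")


# ---------------------------------------------------------------------------
# biomes


@dataclass
class BiomeConfig:
    """Ordered named polygons in (MAT, MAP) space.

    The default configuration ships the package's digitization of the nine
    classic biome polygons.  Points on a shared edge belong to the polygon
    listed first; points outside all polygons are assigned to the nearest
    boundary.
    """

    names: tuple[str, ...]
    polygons: tuple[Polygon, ...]

    @classmethod
    def from_dict(cls, spec: dict, strict: bool = True) -> "BiomeConfig":
        names, polys = [], []
        for entry in spec["biomes"]:
            poly = Polygon(entry["vertices"])
            if not poly.is_valid:
                raise ValidationError(
                    f"biome polygon {entry['name']!r} is not simple"
                )
            names.append(entry["name"])
            polys.append(poly)
        if strict and set(names) != set(NINE_BIOMES):
            raise ValidationError(
                "biome config must name exactly the nine classic biomes"
            )
        return cls(tuple(names), tuple(polys))

    @classmethod
    def from_yaml(cls, path, strict: bool = True) -> "BiomeConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), strict=strict)

    @classmethod
    def default(cls) -> "BiomeConfig":
        ref = resources.files("phylodens").joinpath("data/whittaker_biomes.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def classify_biome(mat: float, map_: float, config: BiomeConfig | None = None,
                   with_flag: bool = False):
    """Biome name for a (MAT, MAP) point.

    A point inside (or on the boundary of) a polygon gets that polygon's
    name, earlier config entries winning ties.  An out-of-polygon point is
    assigned to the nearest polygon; ``with_flag=True`` additionally
    returns whether the point fell inside.
    """
    if map_ < 0:
        raise ValidationError("MAP must be >= 0")
    if config is None:
        config = BiomeConfig.default()
    pt = Point(float(mat), float(map_))
    for name, poly in zip(config.names, config.polygons):
        if poly.covers(pt):
            return (name, True) if with_flag else name
    # nearest boundary, measured with both axes normalized to unit range so
    # millimetres of precipitation do not dominate degrees of temperature
    t_scale, p_scale = 45.0, 4500.0
    pt_n = Point(float(mat) / t_scale, float(map_) / p_scale)
    dists = []
    for poly in config.polygons:
        scaled = Polygon([(x / t_scale, y / p_scale)
                          for x, y in poly.exterior.coords])
        dists.append(scaled.distance(pt_n))
    name = config.names[int(np.argmin(dists))]
    return (name, False) if with_flag else name


def classify_biomes(table: pd.DataFrame, config: BiomeConfig | None = None) -> pd.DataFrame:
    """Annotate a table with ``biome`` and ``biome_inside`` columns."""
    if config is None:
        config = BiomeConfig.default()
    out = table.copy()
    pairs = [classify_biome(m, p, config, with_flag=True)
             for m, p in zip(out["mat"], out["map"])]
    out["biome"] = [p[0] for p in pairs]
    out["biome_inside"] = [p[1] for p in pairs]
    return out


# ---------------------------------------------------------------------------
# group comparison (one-way ANOVA + LSD post hoc, Bonferroni adjusted)


@dataclass
class GroupComparison:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05


def compare_groups(values_by_group: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with LSD pairwise comparisons and a letter display.

    The least-significant-difference tests use the pooled ANOVA mean
    square error; Bonferroni multiplies each pairwise p by the number of
    pairs k(k-1)/2.  Groups sharing a letter are not significantly
    different at ``alpha`` after adjustment.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")

    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(names)

    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ms_between == 0 else math.inf
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within)) if math.isfinite(f) else 0.0

    n_pairs = k * (k - 1) // 2
    rows = []
    sig_pairs = []
    for g1, g2 in combinations(names, 2):
        a, b = groups[g1], groups[g2]
        diff = a.mean() - b.mean()
        se = math.sqrt(ms_within * (1 / a.size + 1 / b.size))
        if se == 0:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        else:
            t = diff / se
        p_raw = 2 * float(stats.t.sf(abs(t), df_within)) if math.isfinite(t) else 0.0
        p_adj = min(1.0, p_raw * n_pairs)
        rows.append({"group1": g1, "group2": g2, "diff": diff, "t": t,
                     "p_raw": p_raw, "p_adj": p_adj})
        if p_adj < alpha:
            sig_pairs.append((g1, g2))
    pairwise = pd.DataFrame(rows)
    letters = _compact_letters(names, groups, sig_pairs)
    return GroupComparison(float(f), p, df_between, df_within, float(ms_within),
                           pairwise, letters, alpha)


def _compact_letters(names, groups, sig_pairs) -> dict[str, str]:
    """Insert-and-absorb compact letter display (highest mean gets 'a')."""
    order = sorted(names, key=lambda g: -groups[g].mean())
    cols: list[set] = [set(order)]
    for g1, g2 in sig_pairs:
        new_cols: list[set] = []
        for col in cols:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop empties, duplicates, and strict subsets
        uniq: list[set] = []
        for col in new_cols:
            if col and col not in uniq:
                uniq.append(col)
        cols = [c for c in uniq if not any(c < o for o in uniq)]
    # letter order follows the position of each column's best-ranked member
    cols.sort(key=lambda col: min(order.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for i, col in enumerate(cols):
        for g in col:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(letters[g])) for g in names}
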