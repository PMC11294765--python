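"""Service-package indicator catalog and facility capability classification.

Continuous maternal and perinatal health care services (CMPHS) are modelled
as three independent service packages — antenatal care (ANC, 7 indicators),
institutional delivery (ID, 8 indicators) and postnatal care (PNC, 10
indicators).  Each health facility carries one boolean readiness flag per
indicator (SARA-style census data); a facility is classified as *capable* of
delivering a package by collapsing that package's flags under an
aggregation rule.  The default rule is ALL (every indicator present): it is
the strictest choice and the only one consistent with package-capable
facility counts falling well below every single indicator's count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
import yaml

__all__ = [
    "PACKAGES",
    "LEVELS",
    "IndicatorCatalog",
    "default_catalog",
    "load_catalog",
    "validate_facility_table",
    "classify_capability",
    "indicator_coverage",
    "level_capability_summary",
    "round_half_up",
]

logger = logging.getLogger(__name__)

PACKAGES = ("ANC", "ID", "PNC")
LEVELS = ("primary", "secondary", "tertiary")

#: Required indicator count per package.
_CARDINALITY = {"ANC": 7, "ID": 8, "PNC": 10}

_DEFAULT_CATALOG = {
    "ANC": [
        "Iron supplementation",
        "Folic acid supplementation",
        "Tetanus toxoid vaccination",
        "Monitoring for hypertensive disorder of pregnancy",
        "IPTp for malaria",
        "HIV counseling and testing for HIV-positive pregnant women",
        "Antiviral treatment for HIV-positive pregnant women",
    ],
    "ID": [
        "Monitoring of labor with partograph",
        "Parenteral administration of oxytocin",
        "Assisted vaginal delivery",
        "Manual removal of placenta",
        "Antibiotics for preterm",
        "Blank partograph",
        "Parenteral administration of magnesium sulfate",
        "Emergency obstetric care",
    ],
    "PNC": [
        "Immediate and exclusive breastfeeding",
        "Thermal protection",
        "Hygenic cord care",
        "Neonatal resuscitation",
        "Kangaroo mother care",
        "Injectable antibiotics for neonatal sepsis",
        "HIV counseling and testing for infants born to HIV-positive women",
        "ARV prophylaxis to newborns of HIV-positive pregnant women",
        "HIV-positive infant and young child feeding counseling",
        "BCG vaccine",
    ],
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (spreadsheet convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_indicator(name: str) -> str:
    """Case- and whitespace-insensitive key for matching flag columns."""
    return " ".join(str(name).split()).lower()


@dataclass(frozen=True)
class IndicatorCatalog:
    """Ordered indicator lists for the three service packages."""

    packages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.packages) != set(PACKAGES):
            raise ValueError(f"catalog must define exactly the packages {PACKAGES}")
        seen: dict[str, str] = {}
        for pkg in PACKAGES:
            names = self.packages[pkg]
            want = _CARDINALITY[pkg]
            if len(names) != want:
                raise ValueError(
                    f"package {pkg} must list {want} indicators, got {len(names)}"
                )
            for name in names:
                key = normalize_indicator(name)
                if key in seen:
                    raise ValueError(
                        f"indicator {name!r} appears in both {seen[key]} and {pkg}"
                    )
                seen[key] = pkg

    def indicators(self, package: str | None = None) -> tuple[str, ...]:
        if package is not None:
            return self.packages[package]
        return tuple(n for pkg in PACKAGES for n in self.packages[pkg])

    def package_of(self, indicator: str) -> str:
        key = normalize_indicator(indicator)
        for pkg in PACKAGES:
            if key in {normalize_indicator(n) for n in self.packages[pkg]}:
                return pkg
        raise KeyError(indicator)


def default_catalog() -> IndicatorCatalog:
    """The built-in 7/8/10 indicator catalog."""
    return IndicatorCatalog(
        packages={pkg: tuple(names) for pkg, names in _DEFAULT_CATALOG.items()}
    )


def load_catalog(config=None) -> IndicatorCatalog:
    """Load a catalog from a mapping, a YAML path, or fall back to the default.

    The document must map each of ANC/ID/PNC to its indicator list; the
    7/8/10 cardinalities and cross-package uniqueness are enforced.
    """
    if config is None:
        return default_catalog()
    if isinstance(config, IndicatorCatalog):
        return config
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("catalog config must be a mapping of package -> indicators")
    doc = config.get("packages", config)
    return IndicatorCatalog(
        packages={str(pkg): tuple(names) for pkg, names in doc.items()}
    )


def validate_facility_table(
    facilities: pd.DataFrame, catalog: IndicatorCatalog
) -> pd.DataFrame:
    """Validate and normalise a facility table against the catalog.

    Expects columns ``facility_id``, ``lon``, ``lat``, ``level`` plus one
    boolean column per catalog indicator (matched after whitespace/case
    normalisation).  Missing indicator columns are imputed as False —
    absence of evidence of readiness — with the imputation count logged.
    """
    required = ["facility_id", "lon", "lat", "level"]
    missing = [c for c in required if c not in facilities.columns]
    if missing:
        raise ValueError(f"facility table missing columns: {missing}")
    out = facilities.copy()
    out["facility_id"] = out["facility_id"].astype(str)
    if out["facility_id"].duplicated().any():
        dups = out.loc[out["facility_id"].duplicated(), "facility_id"].tolist()
        raise ValueError(f"duplicate facility_id: {dups[:5]}")
    lon = pd.to_numeric(out["lon"], errors="raise")
    lat = pd.to_numeric(out["lat"], errors="raise")
    bad = ~(lat.between(-90, 90) & lon.between(-180, 180))
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"coordinate out of range at row {row}: "
            f"lon={lon[row]}, lat={lat[row]}"
        )
    out["lon"], out["lat"] = lon, lat
    unknown_levels = set(out["level"].unique()) - set(LEVELS)
    if unknown_levels:
        raise ValueError(f"unknown facility level(s): {sorted(unknown_levels)}")

    norm_cols = {normalize_indicator(c): c for c in out.columns}
    imputed = 0
    for name in catalog.indicators():
        col = norm_cols.get(normalize_indicator(name))
        if col is None:
            out[name] = False
            imputed += 1
        else:
            out[name] = out[col].astype(bool)
            if col != name:
                out = out.drop(columns=[col])
    if imputed:
        logger.warning("imputed %d missing indicator column(s) as False", imputed)
    return out


def classify_capability(
    facilities: pd.DataFrame,
    catalog: IndicatorCatalog,
    rule: str = "all",
    k: int | None = None,
) -> pd.DataFrame:
    """Collapse per-indicator flags into per-package capability booleans.

    Parameters
    ----------
    rule
        ``"all"`` — capable iff every indicator of the package is present
        (default); ``"any"`` — at least one; ``"at_least_k"`` — at least
        ``k`` (``1 <= k <= |package|``).

    Returns a frame with columns ``facility_id``, ``ANC``, ``ID``, ``PNC``,
    one row per input facility, input order preserved.
    """
    rule = str(rule).lower()
    if rule not in {"all", "any", "at_least_k"}:
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "at_least_k" and k is None:
        raise ValueError("rule 'at_least_k' requires k")
    out = pd.DataFrame({"facility_id": facilities["facility_id"].astype(str)})
    for pkg in PACKAGES:
        flags = facilities[list(catalog.packages[pkg])].astype(bool)
        if rule == "all":
            out[pkg] = flags.all(axis=1)
        elif rule == "any":
            out[pkg] = flags.any(axis=1)
        else:
            size = len(catalog.packages[pkg])
            if not 1 <= k <= size:
                raise ValueError(f"k={k} out of range [1, {size}] for package {pkg}")
            out[pkg] = flags.sum(axis=1) >= k
    return out


def indicator_coverage(
    facilities: pd.DataFrame, catalog: IndicatorCatalog
) -> pd.DataFrame:
    """Per-indicator facility counts and percentages, grouped by package.

    Percent is ``100 * count / N`` rounded half-up to 2 decimals; ordering
    follows the catalog.
    """
    n = len(facilities)
    if n == 0:
        raise ValueError("facility table is empty")
    rows = []
    for pkg in PACKAGES:
        for name in catalog.packages[pkg]:
            count = int(facilities[name].astype(bool).sum())
            rows.append(
                {
                    "package": pkg,
                    "indicator": name,
                    "count": count,
                    "n_facilities": n,
                    "percent": round_half_up(100.0 * count / n),
                }
            )
    return pd.DataFrame(rows)


def level_capability_summary(
    capability: pd.DataFrame, facilities: pd.DataFrame
) -> pd.DataFrame:
    """Capable-facility counts and percentages per level and package.

    One row per (level, package) for levels present in the data, plus
    ``level="all"`` grand-total rows.  Percentages are of the facilities at
    that level, rounded half-up to 2 decimals.
    """
    merged = facilities[["facility_id", "level"]].merge(
        capability, on="facility_id", validate="one_to_one"
    )
    if len(merged) != len(facilities):
        raise ValueError("capability table does not cover all facilities")
    rows = []
    for level in LEVELS:
        sub = merged[merged["level"] == level]
        if sub.empty:
            logger.warning("no facilities at level %r; row omitted", level)
            continue
        for pkg in PACKAGES:
            count = int(sub[pkg].sum())
            rows.append(
                {
                    "level": level,
                    "package": pkg,
                    "count": count,
                    "n_level": len(sub),
                    "percent": round_half_up(100.0 * count / len(sub)),
                }
            )
    for pkg in PACKAGES:
        count = int(merged[pkg].sum())
        rows.append(
            {
                "level": "all",
                "package": pkg,
                "count": count,
                "n_level": len(merged),
                "percent": round_half_up(100.0 * count / len(merged)),
            }
        )
    return pd.DataFrame(rows)
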