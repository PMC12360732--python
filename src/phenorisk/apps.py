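"""App/website canonicalization, communication categories, app-use features.

Online services reachable both as an app and as a website are merged into a
single canonical app key: the domain is extracted from the URL and, when it
appears in a curated domain→package list, replaced by the corresponding
package name; an uncurated domain is used verbatim as the key.  Apps and
websites are then treated identically downstream.

App use is measured from typing: an app counts as "used" on a day when the
participant produced at least one deduplicated text line in it.  The
frequency of an app is

    freq(app) = (# days using the app) / (# days using any app)

and category day-fractions aggregate the same day sets over the messaging /
social-media / dating communication categories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable
from urllib.parse import urlsplit

from .io import MessageLine

__all__ = [
    "AppCategoryMap",
    "CATEGORIES",
    "extract_domain",
    "canonical_app_key",
    "app_frequency_features",
    "category_day_fraction",
    "communication_lines",
]

CATEGORIES = ("messaging", "social_media", "dating", "other")

#: categories whose text is considered communication (text features use only these)
COMMUNICATION_CATEGORIES = frozenset({"messaging", "social_media", "dating"})


def _read_csv_resource(name: str) -> list[dict]:
    ref = importlib_resources.files("phenorisk.resources").joinpath(name)
    with ref.open(newline="") as fh:
        return list(csv.DictReader(fh))


@dataclass
class AppCategoryMap:
    """Canonical app key → communication category, plus curated domain→package pairs.

    The packaged defaults cover widely used messaging, social-media and
    dating apps; both tables are plain CSV and user-replaceable (the original
    study's 68-app list is not public).  Unmapped keys fall back to
    ``"other"``.
    """

    categories: dict[str, str] = field(default_factory=dict)
    domain_to_package: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "AppCategoryMap":
        cats = {r["package"]: r["category"] for r in _read_csv_resource("app_categories.csv")}
        doms = {
            r["domain"]: r["package"] for r in _read_csv_resource("domain_package_map.csv")
        }
        return cls(categories=cats, domain_to_package=doms)

    @classmethod
    def from_files(cls, categories_csv: str | Path, domains_csv: str | Path) -> "AppCategoryMap":
        with open(categories_csv, newline="") as fh:
            cats = {r["package"]: r["category"] for r in csv.DictReader(fh)}
        with open(domains_csv, newline="") as fh:
            doms = {r["domain"]: r["package"] for r in csv.DictReader(fh)}
        return cls(categories=cats, domain_to_package=doms)

    def category(self, key: str) -> str:
        return self.categories.get(key, "other")


def extract_domain(url: str) -> str:
    """Lowercased hostname of a URL, with scheme, credentials, port, path and
    query stripped and a leading ``www.`` removed; empty/unparseable → ``""``."""
    if not url:
        return ""
    raw = url.strip()
    if "://" not in raw and not raw.startswith("//"):
        raw = "//" + raw  # bare domains parse as paths without a scheme marker
    try:
        host = urlsplit(raw).hostname or ""
    except ValueError:
        return ""
    host = host.lower()
    if host.startswith("www."):
        host = host[4:]
    return host


def canonical_app_key(
    package: str, url: str | None, category_map: AppCategoryMap
) -> str:
    """One key per service: curated-domain URLs map to their package, other
    URLs to their domain, native apps to their package name.

    Raises ValueError when both package and url are empty (unattributable
    record).
    """
    if url:
        domain = extract_domain(url)
        if domain:
            return category_map.domain_to_package.get(domain, domain)
    if package:
        return package
    raise ValueError("record has neither package nor url")


def _day_sets(lines: Iterable[MessageLine]) -> dict[str, set]:
    by_app: dict[str, set] = {}
    for ln in lines:
        by_app.setdefault(ln.package, set()).add(ln.day)
    return by_app


def app_frequency_features(lines: Iterable[MessageLine]) -> dict[str, float]:
    """Per-app day-share frequencies for one participant.

    freq(app) = distinct days with a line in the app / distinct days with a
    line in any app.  No active days → empty dict.
    """
    by_app = _day_sets(lines)
    all_days = set().union(*by_app.values()) if by_app else set()
    if not all_days:
        return {}
    return {app: len(days) / len(all_days) for app, days in by_app.items()}


def category_day_fraction(
    lines: Iterable[MessageLine], category_map: AppCategoryMap, category: str
) -> float:
    """Fraction of active days with communication in apps of one category."""
    by_app = _day_sets(lines)
    all_days = set().union(*by_app.values()) if by_app else set()
    if not all_days:
        return 0.0
    cat_days: set = set()
    for app, days in by_app.items():
        if category_map.category(app) == category:
            cat_days |= days
    return len(cat_days) / len(all_days)


def communication_lines(
    lines: Iterable[MessageLine], category_map: AppCategoryMap
) -> list[MessageLine]:
    """Restrict to lines typed in messaging/social-media/dating apps.

    Text from other sources (shopping, navigation, ...) is noise for the
    text feature families and is excluded throughout.
    """
    return [
        ln for ln in lines if category_map.category(ln.package) in COMMUNICATION_CATEGORIES
    ]
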