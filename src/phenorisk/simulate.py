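"""Synthetic cohort generator with planted, configurable class effects.

Emits the three raw event streams a sensing deployment would produce —
keystroke snapshots with incremental-typing and autocorrect artifacts, GPS
traces logged only while moving, and survey answers — for a cohort with
known ground truth, so every pipeline stage can be verified without
participant data.

Planted structure (all ratios configurable):

* outcome labels drawn per prevalence (defaults match an 82-person young
  SGM cohort: methamphetamine use 0.183, ≥6 partners 0.50, condomless
  receptive sex 0.744, injection drug use 0.037);
* participants positive for meth use or ≥6 partners use dating apps on a
  ``dating_ratio``-fold higher share of days and insert sex-related lexicon
  phrases at a ``risky_ratio``-fold higher rate (drug-related phrases are
  driven by meth use);
* participants with ≥6 partners travel ``travel_ratio``-fold farther from
  home;
* condomless receptive sex has no planted behavioral channel, emulating an
  outcome the sensed streams carry little signal for.

Message text is drawn from a template grammar over a neutral vocabulary
with lexicon phrases mixed in at class-dependent rates — controllable and
sufficient for frequency-based features; no natural-language realism is
claimed.  Each participant has an independent RNG stream derived from
(seed, participant index), so cohorts are reproducible under any
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from .io import KeystrokeEvent, LocationFix, SurveyLabel
from .text import PhraseLexicon

__all__ = [
    "SimConfig",
    "CohortData",
    "generate_cohort",
    "generate_typing_trace",
    "generate_day_track",
]

_EPOCH_MS = int(datetime(2023, 1, 1, tzinfo=timezone.utc).timestamp() * 1000)
_DAY_MS = 86_400_000

_NEUTRAL_WORDS = (
    "hey hi hello yeah okay sure thanks cool nice see you tomorrow tonight "
    "later dinner lunch coffee movie show game music song weekend week plan "
    "place time home work school gym store food pizza ride car bus train "
    "meet talk call text send pic photo funny weird busy tired free maybe "
    "definitely soon early late morning night rain sunny cold hot new old "
    "friend people party good great bad fine love miss think know want need "
    "going coming leaving waiting watching playing reading running walking"
).split()

_MESSAGING_APPS = (
    "com.google.android.apps.messaging",
    "com.whatsapp",
    "org.telegram.messenger",
    "com.facebook.orca",
    "com.snapchat.android",
)
_SOCIAL_APPS = (
    "com.instagram.android",
    "com.facebook.katana",
    "com.twitter.android",
    "com.reddit.frontpage",
)
_DATING_APPS = ("com.grindrapp.android", "com.tinder", "com.adam4adam.radar")
_BROWSER = "com.android.chrome"
_APP_DOMAIN = {
    "com.instagram.android": "instagram.com",
    "com.facebook.katana": "facebook.com",
    "com.twitter.android": "x.com",
    "com.grindrapp.android": "grindr.com",
    "com.tinder": "tinder.com",
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 80
    n_days: int = 35
    seed: int = 0
    # outcome prevalences
    p_meth: float = 0.183
    p_partners_6plus: float = 0.50
    p_condomless: float = 0.744
    p_idu: float = 0.037
    # planted effect multipliers (1.0 = no effect)
    dating_ratio: float = 2.5
    risky_ratio: float = 3.0
    travel_ratio: float = 2.5
    # nuisance rates
    missing_rate: float = 0.05
    typo_prob: float = 0.15
    browser_prob: float = 0.10
    # behavior scales
    messages_per_day: float = 6.0
    base_dating_day_rate: float = 0.18
    base_risky_prob: float = 0.04
    n_places: int = 4
    home_visit_share: float = 0.6
    far_trip_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_meth", "p_partners_6plus", "p_condomless", "p_idu",
                     "missing_rate", "typo_prob", "browser_prob",
                     "base_dating_day_rate", "base_risky_prob",
                     "home_visit_share", "far_trip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("dating_ratio", "risky_ratio", "travel_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("cohort must have >=1 participant and >=1 day")


@dataclass
class CohortData:
    keystrokes: list[KeystrokeEvent]
    fixes: list[LocationFix]
    survey: list[SurveyLabel]
    ground_truth: dict = field(repr=False, default_factory=dict)


def generate_typing_trace(
    final_text: str, typo_prob: float, rng: np.random.Generator
) -> list[str]:
    """Keystroke-snapshot text sequence for one typed line.

    Emits the prefix sequence of ``final_text``; with probability
    ``typo_prob`` one intermediate prefix (length ≥ 3) is shown with its
    last character substituted before the corrected prefix follows — the
    autocorrect artifact that breaks the pure-substring pattern.  The last
    row always equals ``final_text``.
    """
    if not final_text:
        raise ValueError("final_text must be nonempty")
    n = len(final_text)
    rows = [final_text[: i + 1] for i in range(n)]
    if n >= 3 and rng.random() < typo_prob:
        alphabet = "abcdefghijklmnopqrstuvwxyz"

        def wrong_char(true_char: str) -> str:
            w = true_char
            while w == true_char:
                w = alphabet[int(rng.integers(len(alphabet)))]
            return w

        if n >= 6:
            # substituted character persists in every later snapshot until the
            # final row corrects the whole line (how autocorrect behaves)
            j = int(rng.integers(2, n - 1))  # 0-based index of the typo'd char
            wrong = wrong_char(final_text[j])
            for k in range(j, n - 1):
                rows[k] = rows[k][:j] + wrong + rows[k][j + 1 :]
        else:
            # short line: a wrong last character shown once, then corrected
            wrong = wrong_char(final_text[-1])
            rows.insert(n - 1, final_text[:-1] + wrong)
    return rows


def _offset_latlon(home: tuple[float, float], dist_mi: float, bearing_rad: float):
    dlat = dist_mi / 69.0 * np.cos(bearing_rad)
    dlon = dist_mi / (69.0 * np.cos(np.radians(home[0]))) * np.sin(bearing_rad)
    return (home[0] + dlat, home[1] + dlon)


def generate_day_track(
    home: tuple[float, float],
    places: Sequence[tuple[float, float]],
    day_start_ms: int,
    rng: np.random.Generator,
    n_outings: int = 1,
) -> list[LocationFix]:
    """Movement-only GPS fixes for one day of place visits.

    Each leg is a burst of fixes 30 s apart interpolating from the origin
    and ending at the destination (±10 m jitter), followed by a silent
    dwell ≥ 1 h; the stay-point detector therefore recovers exactly the
    visited endpoints.  Every outing goes home → place → home, anchoring
    home as the most-visited location.  ``participant_id`` is filled by the
    caller (empty here).
    """
    fixes: list[LocationFix] = []
    t = day_start_ms + int(rng.integers(8, 11)) * 3_600_000

    def leg(src, dst):
        nonlocal t
        n = int(rng.integers(3, 6))
        for k in range(1, n + 1):
            frac = k / n
            lat = src[0] + (dst[0] - src[0]) * frac
            lon = src[1] + (dst[1] - src[1]) * frac
            jitter = 10.0 / 69.0 / 5280.0 * 69.0  # ~10 m in degrees
            lat += float(rng.normal(0, 1e-5))
            lon += float(rng.normal(0, 1e-5))
            t += 30_000
            fixes.append(LocationFix("", t, lat, lon))
        t += int(rng.integers(60, 180)) * 60_000  # dwell 1-3 h

    pos = home
    for _ in range(n_outings):
        if not places:
            break
        dst = places[int(rng.integers(len(places)))]
        leg(pos, dst)
        leg(dst, home)
        pos = home
    return fixes


def _make_message(
    rng: np.random.Generator,
    sex_phrases: list[str],
    drug_phrases: list[str],
    p_sex: float,
    p_drug: float,
) -> tuple[str, int]:
    """One message from the template grammar; returns (text, n_risky)."""
    n = int(rng.integers(3, 9))
    words = [_NEUTRAL_WORDS[int(rng.integers(len(_NEUTRAL_WORDS)))] for _ in range(n)]
    n_risky = 0
    if sex_phrases and rng.random() < p_sex:
        words.insert(int(rng.integers(len(words) + 1)), sex_phrases[int(rng.integers(len(sex_phrases)))])
        n_risky += 1
    if drug_phrases and rng.random() < p_drug:
        words.insert(int(rng.integers(len(words) + 1)), drug_phrases[int(rng.integers(len(drug_phrases)))])
        n_risky += 1
    return " ".join(words), n_risky


def generate_cohort(config: SimConfig) -> CohortData:
    """Generate the three event logs plus ground truth for one cohort."""
    lexicon = PhraseLexicon.default()
    sex_phrases = sorted({" ".join(p) for p, c, _ in lexicon.entries if c == "sex_related"})
    drug_phrases = sorted({" ".join(p) for p, c, _ in lexicon.entries if c == "drug_related"})

    keystrokes: list[KeystrokeEvent] = []
    fixes: list[LocationFix] = []
    survey: list[SurveyLabel] = []
    truth: dict = {}

    for idx in range(config.n_participants):
        rng = np.random.default_rng([config.seed % (2**31), idx])
        pid = f"P{idx:03d}"

        meth = rng.random() < config.p_meth
        partners = rng.random() < config.p_partners_6plus
        condomless = rng.random() < config.p_condomless
        idu = meth and (rng.random() < config.p_idu / max(config.p_meth, 1e-9))

        sex_mult = config.risky_ratio if (meth or partners) else 1.0
        drug_mult = config.risky_ratio if meth else 1.0
        dating_rate = min(
            0.95,
            config.base_dating_day_rate * (config.dating_ratio if (meth or partners) else 1.0),
        )
        travel_scale = config.travel_ratio if partners else 1.0

        # places around a random home in the continental US
        home = (float(rng.uniform(30.0, 45.0)), float(rng.uniform(-120.0, -75.0)))
        places = [
            _offset_latlon(
                home, float(rng.uniform(0.5, 5.0)) * travel_scale, float(rng.uniform(0, 2 * np.pi))
            )
            for _ in range(config.n_places)
        ]
        far_place = _offset_latlon(
            home, float(rng.uniform(60.0, 120.0)) * travel_scale, float(rng.uniform(0, 2 * np.pi))
        )

        apps_msg = list(rng.choice(_MESSAGING_APPS, size=2, replace=False))
        app_social = str(rng.choice(_SOCIAL_APPS))
        app_dating = str(rng.choice(_DATING_APPS))

        n_risky_total = 0
        final_texts: list[str] = []
        for day in range(config.n_days):
            day_start = _EPOCH_MS + day * _DAY_MS
            dating_day = rng.random() < dating_rate
            social_day = rng.random() < 0.6
            day_apps = [apps_msg[int(rng.integers(len(apps_msg)))]]
            if social_day:
                day_apps.append(app_social)
            if dating_day:
                day_apps.append(app_dating)

            n_msgs = max(1, int(rng.poisson(config.messages_per_day)))
            t = day_start + int(rng.integers(9, 13)) * 3_600_000
            for _ in range(n_msgs):
                app = day_apps[int(rng.integers(len(day_apps)))]
                text, n_risky = _make_message(
                    rng,
                    sex_phrases,
                    drug_phrases,
                    min(0.9, config.base_risky_prob * sex_mult),
                    min(0.9, config.base_risky_prob * drug_mult),
                )
                n_risky_total += n_risky
                final_texts.append(text)
                url = None
                package = app
                if app in _APP_DOMAIN and rng.random() < config.browser_prob:
                    package = _BROWSER
                    url = f"https://www.{_APP_DOMAIN[app]}/m"
                for row in generate_typing_trace(text, config.typo_prob, rng):
                    keystrokes.append(KeystrokeEvent(pid, t, package, row, url))
                    t += 150
                t += int(rng.integers(60, 600)) * 1000  # gap to the next message

            # location: most days one outing home -> place -> home
            n_outings = int(rng.poisson(1.0)) + (1 if rng.random() < 0.7 else 0)
            day_places = places
            if rng.random() < min(0.9, config.far_trip_prob * travel_scale):
                day_places = places + [far_place]
            track = generate_day_track(home, day_places, day_start, rng, n_outings=n_outings)
            fixes.extend(
                LocationFix(pid, f.timestamp, f.lat, f.lon) for f in track
            )

        # survey answers in the raw wellness-survey schema
        def respond(question: str, answer: str) -> None:
            if rng.random() < config.missing_rate:
                answer = "decline"
            survey.append(SurveyLabel(pid, question, answer))

        substance = {
            (False, False): "none",
            (True, False): "meth",
            (False, True): "idu",
            (True, True): "meth_and_idu",
        }[(meth, idu)]
        respond("substance_use", substance)
        if partners:
            respond("partners_count", "11_plus" if rng.random() < 0.35 else "6_10")
        else:
            respond("partners_count", "2_5" if rng.random() < 0.7 else "0_1")
        respond("condomless_receptive", "yes" if condomless else "no")
        respond("in_treatment", "no")

        truth[pid] = {
            "labels": {
                "meth_use": meth,
                "partners_6plus": partners,
                "condomless_receptive": condomless,
                "idu": idu,
            },
            "home": home,
            "places": places,
            "n_risky_insertions": n_risky_total,
            "final_texts": final_texts,
        }

    keystrokes.sort(key=lambda e: (e.participant_id, e.timestamp))
    fixes.sort(key=lambda f: (f.participant_id, f.timestamp))
    return CohortData(keystrokes, fixes, survey, truth)
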