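"""Synthetic DRG catalogs and note-level cohorts with planted, time-accruing signal.

Real DRG-labelled ICU note corpora are access-restricted, so this module
generates a stand-in with the structural features the downstream pipeline
depends on: two DRG systems (a flat MS-style code space and an APR-style
group x 4-severity space), Zipf-like code frequencies, lognormal-like
relative weights, notes accruing from -24 to 48 hours around ICU admission,
and DRG-indicative token n-grams whose emission probability grows linearly
with chart time.  Every generated quantity is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MS_LIKE = "MS_LIKE"
APR_LIKE = "APR_LIKE"
SYSTEMS = (MS_LIKE, APR_LIKE)

NOTE_CATEGORIES = ("nursing", "physician", "radiology", "other")
_CATEGORY_PROBS = (0.5, 0.2, 0.15, 0.15)

#: Severity multipliers for APR-style codes; strictly increasing with mean 1.0
#: so the catalog-level mean weight matches the configured target.
APR_SEVERITY_MULTIPLIERS = (0.5, 0.8, 1.1, 1.6)

_MDC_POOL = ("MDC01", "MDC04", "MDC05", "MDC06", "MDC08", "MDC18")

_DEID_SNIPPETS = (
    "[**Name (NI) 1234**]",
    "[**Hospital1 5**]",
    "[**2101-4-12**]",
    "[**Last Name (un) 77**]",
)


class InvalidConfigError(ValueError):
    """Raised when a GenConfig violates its own invariants."""


class EmptyCatalogError(ValueError):
    """Raised when cohort simulation is asked to sample from an empty catalog."""


class TableIOError(OSError):
    """Raised when a cohort table cannot be written or read; names the file."""


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    system: str
    mdc: str
    severity: int | None
    weight: float
    description: str
    signal_ngrams: tuple[tuple[str, ...], ...] = ()


@dataclass
class DrgCatalog:
    """The prediction target space: DRG codes with weights and planted n-grams."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        self._by_code = {e.code: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> CatalogEntry:
        return self._by_code[code]

    def codes(self, system: str | None = None) -> list[str]:
        return [e.code for e in self.entries if system is None or e.system == system]

    def weight_of(self, code: str) -> float:
        return self._by_code[code].weight


@dataclass(frozen=True)
class NoteEvent:
    stay_id: str
    chart_hpa: float  # hours relative to ICU admission; negative = pre-ICU
    category: str
    text: str


@dataclass(frozen=True)
class StayRecord:
    """One hospital stay with its timestamped notes and assigned DRG."""

    stay_id: str
    patient_id: str
    age: int
    n_icu_visits: int
    notes: tuple[NoteEvent, ...]
    drg_system: str
    drg_code: str
    true_weight: float
    admission_index: int = 0  # monotone order of the patient's admissions


@dataclass(frozen=True)
class GenConfig:
    """Knobs of the generative model.

    Weight targets default to mean 3.0 / SD 2.8, the scale of relative weights
    in adult ICU populations.  ``signal_rate_slope`` is the per-hour increase in
    the probability that a token slot emits one of the stay's DRG-indicative
    n-grams, anchored at zero at -24 h.
    """

    seed: int
    n_patients: int = 1000
    n_drg_groups: int = 10
    system: str = MS_LIKE
    zipf_exponent: float = 1.2
    weight_mean: float = 3.0
    weight_sd: float = 2.8
    background_vocab_size: int = 2000
    signal_rate_slope: float = 0.002
    note_rate: float = 1.0  # expected notes per 6-h interval
    note_len_mean: float = 30.0
    frac_under18: float = 0.05
    frac_multi_icu: float = 0.10
    frac_repeat_patients: float = 0.15
    deid_placeholder_rate: float = 0.3

    def validate(self) -> None:
        if self.system not in SYSTEMS:
            raise InvalidConfigError(f"unknown system {self.system!r}")
        if self.n_drg_groups < 2:
            raise InvalidConfigError("n_drg_groups must be >= 2")
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        for name in ("frac_under18", "frac_multi_icu", "frac_repeat_patients",
                     "deid_placeholder_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.weight_mean <= 0 or self.weight_sd <= 0:
            raise InvalidConfigError("weight_mean and weight_sd must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _group_ngrams(gid: int, severity: int | None) -> tuple[tuple[str, ...], ...]:
    # Two n-grams per code, built from tokens unique to the base group; the
    # severity marker token makes APR codes separable within a group.
    a, b, c, d, e = (f"g{gid}{s}" for s in "abcde")
    if severity is None:
        return ((a, b, c), (d, e, c))
    sev = f"sev{severity}"
    return ((a, b, sev), (d, e, sev))


def make_drg_catalog(config: GenConfig) -> DrgCatalog:
    """Build a synthetic DRG catalog for ``config.system``.

    MS-style catalogs hold one code per group; APR-style catalogs expand each
    group into four severity tiers with strictly increasing weights.  Weights
    are lognormal draws (clipped below) calibrated so the catalog-level mean
    and SD converge to ``weight_mean`` / ``weight_sd`` as the catalog grows.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 101])
    n = config.n_drg_groups
    mdcs = rng.choice(len(_MDC_POOL), size=n)

    entries: list[CatalogEntry] = []
    if config.system == MS_LIKE:
        mu, sigma = _lognormal_params(config.weight_mean, config.weight_sd)
        weights = np.maximum(rng.lognormal(mu, sigma, size=n), 0.2)
        for g in range(n):
            toks = " ".join(t for ng in _group_ngrams(g, None) for t in ng)
            entries.append(CatalogEntry(
                code=f"MS{g + 1:03d}",
                system=MS_LIKE,
                mdc=_MDC_POOL[mdcs[g]],
                severity=None,
                weight=round(float(weights[g]), 4),
                description=f"{_MDC_POOL[mdcs[g]]} synthetic condition group {g + 1} ({toks})",
                signal_ngrams=_group_ngrams(g, None),
            ))
    else:
        # Per-group base draw; the severity multipliers have mean 1 and mean
        # square m2, so base SD is deflated to keep the catalog SD on target.
        m2 = float(np.mean(np.square(APR_SEVERITY_MULTIPLIERS)))
        target_var = (config.weight_mean**2 + config.weight_sd**2) / m2 - config.weight_mean**2
        base_sd = float(np.sqrt(max(target_var, 1e-4)))
        mu, sigma = _lognormal_params(config.weight_mean, base_sd)
        bases = np.maximum(rng.lognormal(mu, sigma, size=n), 0.4)
        for g in range(n):
            for s in range(1, 5):
                w = round(float(bases[g] * APR_SEVERITY_MULTIPLIERS[s - 1]), 4)
                toks = " ".join(t for ng in _group_ngrams(g, s) for t in ng)
                entries.append(CatalogEntry(
                    code=f"AP{g + 1:03d}-{s}",
                    system=APR_LIKE,
                    mdc=_MDC_POOL[mdcs[g]],
                    severity=s,
                    weight=w,
                    description=(f"{_MDC_POOL[mdcs[g]]} synthetic condition group {g + 1} "
                                 f"severity {s} ({toks})"),
                    signal_ngrams=_group_ngrams(g, s),
                ))
    return DrgCatalog(entries)


def _background_cumprobs(vocab_size: int, exponent: float = 1.1) -> np.ndarray:
    p = np.arange(1, vocab_size + 1, dtype=float) ** (-exponent)
    return np.cumsum(p / p.sum())


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    p = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return p / p.sum()


def _make_note_text(rng: np.random.Generator, entry: CatalogEntry, hpa: float,
                    config: GenConfig, bg_cum: np.ndarray) -> str:
    n_slots = 3 + int(rng.poisson(max(config.note_len_mean - 3, 0.5)))
    p_sig = float(np.clip(config.signal_rate_slope * (hpa + 24.0), 0.0, 1.0))
    sig_draws = rng.random(n_slots)
    bg_ids = np.searchsorted(bg_cum, rng.random(n_slots))
    ngram_pick = rng.integers(0, len(entry.signal_ngrams), size=n_slots)
    tokens: list[str] = []
    for i in range(n_slots):
        if sig_draws[i] < p_sig:
            tokens.extend(entry.signal_ngrams[ngram_pick[i]])
        else:
            tokens.append(f"w{bg_ids[i]}")
    if rng.random() < config.deid_placeholder_rate:
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, _DEID_SNIPPETS[int(rng.integers(0, len(_DEID_SNIPPETS)))])
    return " ".join(tokens)


def simulate_cohort(catalog: DrgCatalog, config: GenConfig) -> list[StayRecord]:
    """Simulate ``config.n_patients`` patients with DRG-labelled, note-bearing stays.

    DRGs are sampled by Zipf rank frequency over the catalog order; notes are
    Poisson-placed in 6-h bins covering [-24, 48) h around ICU admission; each
    token slot emits a signal n-gram of the stay's DRG with probability growing
    linearly in chart time.  Configured fractions of under-18 patients,
    multi-ICU-visit stays and repeat patients are realised in expectation.
    """
    config.validate()
    if len(catalog) == 0:
        raise EmptyCatalogError("cannot simulate stays from an empty catalog")
    rng = np.random.default_rng([int(config.seed) % (2**31), 202])
    code_probs = _zipf_probs(len(catalog), config.zipf_exponent)
    bg_cum = _background_cumprobs(config.background_vocab_size)
    cat_idx = np.arange(len(catalog))

    stays: list[StayRecord] = []
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        if rng.random() < config.frac_under18:
            age = int(rng.integers(1, 18))  # strictly under 18
        else:
            age = int(rng.integers(19, 91))
        n_stays = 2 if rng.random() < config.frac_repeat_patients else 1
        for k in range(n_stays):
            stay_id = f"{pid}-{k}"
            n_icu = int(rng.integers(2, 4)) if rng.random() < config.frac_multi_icu else 1
            entry = catalog.entries[int(rng.choice(cat_idx, p=code_probs))]
            notes: list[NoteEvent] = []
            for bin_start in range(-24, 48, 6):
                for _ in range(int(rng.poisson(config.note_rate))):
                    hpa = round(float(bin_start + 6.0 * rng.random()), 2)
                    cat = NOTE_CATEGORIES[int(rng.choice(4, p=_CATEGORY_PROBS))]
                    notes.append(NoteEvent(stay_id, hpa, cat,
                                           _make_note_text(rng, entry, hpa, config, bg_cum)))
            stays.append(StayRecord(
                stay_id=stay_id,
                patient_id=pid,
                age=age,
                n_icu_visits=n_icu,
                notes=tuple(notes),
                drg_system=entry.system,
                drg_code=entry.code,
                true_weight=entry.weight,
                admission_index=k,
            ))
    return stays


# ---------------------------------------------------------------------------
# CSV tables (UTF-8, header row, RFC-4180 quoting via the csv module)

NOTES_HEADER = ["stay_id", "patient_id", "chart_hpa", "category", "text"]
ASSIGN_HEADER = ["stay_id", "patient_id", "age", "n_icu_visits", "drg_system", "drg_code"]
CATALOG_HEADER = ["drg_code", "drg_system", "mdc", "severity", "weight", "description"]


def write_tables(stays: Sequence[StayRecord], catalog: DrgCatalog,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write notes.csv, drg_assignments.csv and catalog.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("notes", "drg_assignments", "catalog")}
    try:
        with open(paths["notes"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(NOTES_HEADER)
            for s in stays:
                for n in s.notes:
                    w.writerow([n.stay_id, s.patient_id, repr(n.chart_hpa), n.category, n.text])
        with open(paths["drg_assignments"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(ASSIGN_HEADER)
            for s in stays:
                w.writerow([s.stay_id, s.patient_id, s.age, s.n_icu_visits,
                            s.drg_system, s.drg_code])
        with open(paths["catalog"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(CATALOG_HEADER)
            for e in catalog.entries:
                w.writerow([e.code, e.system, e.mdc,
                            "" if e.severity is None else e.severity,
                            repr(e.weight), e.description])
    except OSError as exc:
        raise TableIOError(f"failed writing table under {out}: {exc}") from exc
    return paths


def read_catalog(path: str | Path) -> DrgCatalog:
    entries = []
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(CatalogEntry(
                    code=row["drg_code"],
                    system=row["drg_system"],
                    mdc=row["mdc"],
                    severity=int(row["severity"]) if row["severity"] else None,
                    weight=float(row["weight"]),
                    description=row["description"],
                ))
    except OSError as exc:
        raise TableIOError(f"failed reading {path}: {exc}") from exc
    return DrgCatalog(entries)


def read_tables(in_dir: str | Path) -> tuple[list[StayRecord], DrgCatalog]:
    """Inverse of :func:`write_tables`; stays round-trip field-for-field.

    The admission index is recovered from lexicographic stay-id order within
    each patient (stay ids carry a monotone ``-<k>`` suffix).
    """
    in_dir = Path(in_dir)
    catalog = read_catalog(in_dir / "catalog.csv")
    notes_by_stay: dict[str, list[NoteEvent]] = {}
    try:
        with open(in_dir / "notes.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                notes_by_stay.setdefault(row["stay_id"], []).append(
                    NoteEvent(row["stay_id"], float(row["chart_hpa"]),
                              row["category"], row["text"]))
        stays: list[StayRecord] = []
        order_within_patient: dict[str, int] = {}
        with open(in_dir / "drg_assignments.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                pid = row["patient_id"]
                idx = order_within_patient.get(pid, 0)
                order_within_patient[pid] = idx + 1
                code = row["drg_code"]
                stays.append(StayRecord(
                    stay_id=row["stay_id"],
                    patient_id=pid,
                    age=int(row["age"]),
                    n_icu_visits=int(row["n_icu_visits"]),
                    notes=tuple(notes_by_stay.get(row["stay_id"], ())),
                    drg_system=row["drg_system"],
                    drg_code=code,
                    true_weight=catalog.weight_of(code) if code in catalog else float("nan"),
                    admission_index=idx,
                ))
    except OSError as exc:
        raise TableIOError(f"failed reading tables under {in_dir}: {exc}") from exc
    return stays, catalog
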