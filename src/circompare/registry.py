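"""Central registry of the 18 two-sample tests, keyed by abbreviation.

Null-hypothesis classes: 8 tests of identical distribution, 5 of identical
mean/median, 5 of identical concentration.  ``ROBUST8`` is the subset that
controls Type-I error across all benchmark situations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .core import TestResult
from . import concentration as _conc
from . import identity as _ident
from . import meandir as _mean

NULL_IDENTITY = "identical-distribution"
NULL_MEAN = "identical-mean"
NULL_CONC = "identical-concentration"

__all__ = ["TestEntry", "REGISTRY", "ROBUST8", "run_test", "resolve_tests"]


@dataclass(frozen=True)
class TestEntry:
    test_id: str
    name: str
    null_class: str
    func: Callable  # (s1, s2) -> TestResult


def _rpo(s1, s2) -> TestResult:
    return _mean.rao_homogeneity(s1, s2)[0]


def _rdi(s1, s2) -> TestResult:
    return _mean.rao_homogeneity(s1, s2)[1]


def _mww(s1, s2) -> TestResult:
    return _ident.uniform_scores_test(s1, s2, variant="MWW")


def _wwe(s1, s2) -> TestResult:
    return _ident.uniform_scores_test(s1, s2, variant="WWe")


_ENTRIES = [
    # identical distribution
    TestEntry("WU2", "Watson's U2 test", NULL_IDENTITY, _ident.watson_u2),
    TestEntry("Kui", "Kuiper two-sample test", NULL_IDENTITY, _ident.kuiper_two),
    TestEntry("MWW", "Large-sample Mardia-Watson-Wheeler test", NULL_IDENTITY, _mww),
    TestEntry("WWe", "Watson-Wheeler test", NULL_IDENTITY, _wwe),
    TestEntry("EmA", "Embedding approach ANOVA", NULL_IDENTITY, _ident.embedding_anova),
    TestEntry("LlA", "Log-likelihood ratio ANOVA", NULL_IDENTITY, _ident.lr_anova),
    TestEntry("HeA", "Non-equal concentration parameters ANOVA", NULL_IDENTITY, _ident.het_anova),
    TestEntry("Man", "MANOVA approach", NULL_IDENTITY, _ident.manova_trig),
    # identical mean/median
    TestEntry("WWi", "Watson-Williams test", NULL_MEAN, _mean.watson_williams),
    TestEntry("Wat", "Watson's large-sample nonparametric test", NULL_MEAN, _mean.watson_large_sample),
    TestEntry("FPg", "Fisher's nonparametric common-median test", NULL_MEAN, _mean.fisher_common_median),
    TestEntry("Pt", "P-test (asymptotic)", NULL_MEAN, _mean.p_test_asymptotic),
    TestEntry("Rpo", "Rao polar test", NULL_MEAN, _rpo),
    # identical concentration
    TestEntry("Con", "Concentration test", NULL_CONC, _conc.concentration_f_test),
    TestEntry("FM", "Fisher's method (tangential)", NULL_CONC, _conc.fisher_concentration),
    TestEntry("Lev", "Levene's test (fixed frame)", NULL_CONC, _conc.levene_circular),
    TestEntry("Rdi", "Rao dispersion test", NULL_CONC, _rdi),
    TestEntry("Wal", "Wallraff test", NULL_CONC, _conc.wallraff),
]

REGISTRY: dict[str, TestEntry] = {e.test_id: e for e in _ENTRIES}

ROBUST8 = ("WU2", "MWW", "WWe", "EmA", "Man", "Rpo", "Lev", "Con")


def run_test(test_id: str, s1, s2) -> TestResult:
    """Run one registered test by its abbreviation."""
    try:
        entry = REGISTRY[test_id]
    except KeyError:
        raise KeyError(f"unknown test id {test_id!r}; known: {sorted(REGISTRY)}") from None
    return entry.func(s1, s2)


def resolve_tests(which) -> tuple[str, ...]:
    """Expand a test selection ('all', 'robust8', iterable or comma string)."""
    if which is None or which == "all":
        return tuple(REGISTRY)
    if which == "robust8":
        return ROBUST8
    if isinstance(which, str):
        ids = tuple(t.strip() for t in which.split(",") if t.strip())
    else:
        ids = tuple(which)
    for tid in ids:
        if tid not in REGISTRY:
            raise KeyError(f"unknown test id {tid!r}; known: {sorted(REGISTRY)}")
    return ids
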