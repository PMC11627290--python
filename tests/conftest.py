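import numpy as np
import pytest
import scipy.sparse as sp

import phenomine as pm


@pytest.fixture
def two_term_dict() -> pm.TermDictionary:
    return pm.TermDictionary(
        [
            pm.TermEntry("Graying of hair", ["Gray Hair"]),
            pm.TermEntry("Dementia"),
        ],
        name="two_terms",
    )


@pytest.fixture
def clinical_dict() -> pm.TermDictionary:
    """Six clinical terms with synonyms, mimicking a seed-term dictionary."""
    return pm.TermDictionary(
        [
            pm.TermEntry("Graying of hair", ["Gray Hair", "grey hair"]),
            pm.TermEntry("Dementia", ["senile dementia"]),
            pm.TermEntry("Cataract", ["lens opacity"]),
            pm.TermEntry("Hypertension", ["high blood pressure"]),
            pm.TermEntry("Osteoporosis", ["bone loss"]),
            pm.TermEntry("Sarcopenia", ["muscle wasting"]),
        ],
        name="clinical",
    )


@pytest.fixture
def keyword_dict() -> pm.TermDictionary:
    return pm.default_aging_keywords()


def presence_matrix(rows, cols, cells) -> pm.TermDocMatrix:
    """Build a presence TermDocMatrix from a set of (row_label, col_label)."""
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    m = np.zeros((len(rows), len(cols)), dtype=int)
    for r, c in cells:
        m[ri[r], ci[c]] = 1
    return pm.TermDocMatrix(list(rows), list(cols), sp.csr_matrix(m), "presence")


@pytest.fixture
def filter_fixture():
    """A 50-abstract corpus with hand-controlled term/keyword presences.

    Returns (term_matrix, keyword_matrix, term_presences, keyword_flags)
    where presences/flags are the plain-python ground truth used by the
    brute-force oracle.
    """
    rng = np.random.default_rng(7)
    terms = ["Dementia", "Cataract", "Hypertension", "Osteoporosis"]
    ids = [f"A{i:02d}" for i in range(50)]
    term_presences = {
        aid: {t for t in terms if rng.random() < 0.35} for aid in ids
    }
    keyword_flags = {aid: bool(rng.random() < 0.4) for aid in ids}
    tmat = presence_matrix(
        terms, ids, [(t, aid) for aid, ts in term_presences.items() for t in ts]
    )
    kmat = presence_matrix(
        ["aging"], ids, [("aging", aid) for aid, f in keyword_flags.items() if f]
    )
    return tmat, kmat, term_presences, keyword_flags
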