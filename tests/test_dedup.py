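"""TF-IDF vectors, cosine, and the syndication labeling rule."""

import datetime as dt
import math
import random
from collections import Counter

import numpy as np
import pytest
from scipy.sparse import csr_matrix

import taxatalk as tt
from taxatalk.records import tokenize


def art(aid, body, day, url=None, month=1):
    return tt.ArticleRecord(aid, f"t{aid}", url or f"https://x.com/{aid}",
                            date=dt.date(2019, month, day), body=body)


# ---------------------------------------------------------------------------
# tfidf / cosine

def _hand_tfidf(texts):
    """Independent evaluation of tf-idf: tf = raw count,
    idf = ln((1+N)/(1+df)) + 1, L2-normalized, sorted vocabulary."""
    docs = [tokenize(t) for t in texts]
    vocab = sorted({w for d in docs for w in d})
    n = len(docs)
    df = {w: sum(w in d for d in docs) for w in vocab}
    rows = []
    for d in docs:
        counts = Counter(d)
        vec = [counts[w] * (math.log((1 + n) / (1 + df[w])) + 1) for w in vocab]
        norm = math.sqrt(sum(x * x for x in vec))
        rows.append([x / norm if norm else 0.0 for x in vec])
    return np.array(rows), vocab


def test_tfidf_three_doc_toy_matches_hand_values():
    texts = ["cat sat", "cat ran", "dog ran ran"]
    matrix, vec = tt.tfidf_vectors(texts)
    want, vocab = _hand_tfidf(texts)
    names = list(vec.get_feature_names_out())
    assert names == vocab
    assert np.allclose(matrix.toarray(), want, atol=1e-12)


def test_tfidf_single_document_proportional_to_counts():
    matrix, vec = tt.tfidf_vectors(["bat bat cave"])
    row = matrix.toarray()[0]
    names = list(vec.get_feature_names_out())
    assert row[names.index("bat")] == pytest.approx(2 * row[names.index("cave")])
    assert np.linalg.norm(row) == pytest.approx(1.0)


def test_tfidf_idf_monotone_in_df():
    texts = ["shared rare", "shared other", "shared third"]
    matrix, vec = tt.tfidf_vectors(texts)
    idf = dict(zip(vec.get_feature_names_out(), vec.idf_))
    assert idf["shared"] < idf["rare"]


def test_cosine_identical_disjoint_and_hand_value():
    m, _ = tt.tfidf_vectors(["green lizard basking", "green lizard basking"])
    assert tt.cosine(m[0], m[1]) == pytest.approx(1.0)
    m2, _ = tt.tfidf_vectors(["alpha beta", "gamma delta"])
    assert tt.cosine(m2[0], m2[1]) == 0.0
    u = csr_matrix(np.array([[1.0, 1.0, 0.0]]) / math.sqrt(2))
    v = csr_matrix(np.array([[1.0, 0.0, 1.0]]) / math.sqrt(2))
    assert tt.cosine(u, v) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# syndication labeling

def test_verbatim_copy_within_window_is_syndicate():
    a = art("a", "The pangolin was rescued near the reserve fence.", 1)
    b = art("b", "The pangolin was rescued near the reserve fence.", 11)
    c = art("c", "Completely different storyline about elections and tax.", 5)
    labels = {l.article_id: l for l in tt.flag_syndicates([b, c, a])}
    assert labels["a"].status == "original"
    assert labels["b"].status == "syndicate" and labels["b"].parent_id == "a"
    assert labels["c"].status == "original"


def test_verbatim_copy_outside_window_is_original():
    a = art("a", "The pangolin was rescued near the reserve fence.", 1)
    b = art("b", "The pangolin was rescued near the reserve fence.", 1, month=4)
    labels = {l.article_id: l for l in tt.flag_syndicates([a, b])}
    assert labels["a"].status == "original"
    assert labels["b"].status == "original"


def test_all_distinct_corpus_all_original():
    arts = [art(f"a{i}", f"unique topic {i} about item{i} only", i + 1)
            for i in range(5)]
    assert all(l.status == "original" for l in tt.flag_syndicates(arts))


def test_chain_parent_is_earliest_in_window():
    # A at day 1, B = copy at +14d, C = copy at +70d from A: C sees only B.
    text = "The horseshoe bat colony roosts in the old mine shaft nightly."
    a = art("a", text, 1)
    b = art("b", text, 15)
    c = tt.ArticleRecord("c", "tc", "https://x.com/c",
                         date=dt.date(2019, 3, 12), body=text)
    labels = {l.article_id: l for l in tt.flag_syndicates([a, b, c])}
    assert labels["b"].parent_id == "a"
    assert labels["c"].status == "syndicate" and labels["c"].parent_id == "b"
    # chain-root mode re-links C to the original A
    rooted = {l.article_id: l for l in
              tt.flag_syndicates([a, b, c], parents_original_only=True)}
    assert rooted["c"].parent_id == "a"


def test_undated_articles_excluded():
    a = art("a", "body text here", 1)
    b = tt.ArticleRecord("b", "t", "https://x.com/b", body="body text here")
    labels = tt.flag_syndicates([a, b])
    assert [l.article_id for l in labels] == ["a"]


def _random_corpus(rng, n):
    pool = [f"w{i}" for i in range(30)]
    arts = []
    for i in range(n):
        if arts and rng.random() < 0.3:
            parent = rng.choice(arts)
            body = parent.body
        else:
            body = " ".join(rng.choices(pool, k=rng.randint(5, 15)))
        arts.append(art(f"a{i:03d}", body, rng.randint(1, 28),
                        month=rng.randint(1, 5)))
    return arts


def _oracle_labels(arts, threshold, window_days):
    """All-pairs brute force: independent tf-idf, every in-window pair
    compared, later of each > threshold pair marked syndicate."""
    from taxatalk.querygen import normalize_url
    order = sorted(arts, key=lambda a: (a.date, normalize_url(a.url)))
    mat, _ = _hand_tfidf([a.body for a in order])
    out = {}
    for i, a in enumerate(order):
        parent, best = None, 0.0
        for j in range(i):
            if (a.date - order[j].date).days > window_days:
                continue
            s = float(mat[i] @ mat[j])
            best = max(best, s)
            if s > threshold and parent is None:
                parent = order[j].article_id
        out[a.article_id] = ("syndicate" if parent else "original", parent, best)
    return out


def test_flag_syndicates_matches_brute_force_oracle():
    rng = random.Random(4)
    for _ in range(15):
        arts = _random_corpus(rng, rng.randint(2, 100))
        got = {l.article_id: l for l in tt.flag_syndicates(arts)}
        want = _oracle_labels(arts, 0.95, 60)
        assert set(got) == set(want)
        for aid, (status, parent, best) in want.items():
            assert got[aid].status == status
            assert got[aid].parent_id == parent
            assert got[aid].max_similarity == pytest.approx(best, abs=1e-9)
        # bookkeeping invariants
        n_orig = sum(l.status == "original" for l in got.values())
        n_synd = sum(l.status == "syndicate" for l in got.values())
        assert n_orig + n_synd == len(arts)
        by_id = {a.article_id: a for a in arts}
        for l in got.values():
            if l.parent_id is not None:
                assert by_id[l.parent_id].date <= by_id[l.article_id].date


def test_threshold_monotonicity():
    rng = random.Random(5)
    arts = _random_corpus(rng, 60)
    counts = []
    for thr in (0.5, 0.7, 0.9, 0.95, 0.99):
        labels = tt.flag_syndicates(arts, threshold=thr)
        counts.append(sum(l.status == "syndicate" for l in labels))
    assert counts == sorted(counts, reverse=True)
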