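import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phylohgt.screen import (
    HomologHit,
    ScreenConfig,
    coverage,
    drop_organelle_genes,
    filter_hits,
    flag_contamination,
    read_hits,
    screen,
)
from phylohgt.synthetic import simulate_hits, simulate_organelle_annotations


def make_hit(pident=50.0, qcov=0.9, scov=0.9, qlen=200, slen=200, query="q", subject="s"):
    qspan = max(1, round(qcov * qlen))
    sspan = max(1, round(scov * slen))
    return HomologHit(
        query_id=query, subject_id=subject, pident=pident,
        qstart=1, qend=qspan, sstart=1, send=sspan, qlen=qlen, slen=slen,
    )


@pytest.mark.parametrize(
    "qstart,qend,qlen,expected_qcov",
    [(1, 100, 100, 1.0), (11, 90, 100, 0.80), (1, 80, 100, 0.80)],
)
def test_coverage_from_coordinates(qstart, qend, qlen, expected_qcov):
    hit = HomologHit(
        query_id="q", subject_id="s", pident=50,
        qstart=qstart, qend=qend, qlen=qlen, sstart=1, send=80, slen=100,
    )
    qcov, scov = coverage(hit)
    assert qcov == pytest.approx(expected_qcov)
    assert scov == pytest.approx(0.80)


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        make_hit(qcov=1.2)  # qend beyond qlen


@pytest.mark.parametrize(
    "pident,qcov,scov,kept",
    [
        (35.0, 0.85, 0.90, True),    # identity bound is inclusive
        (34.9, 0.95, 0.95, False),
        (60.0, 0.80, 0.90, False),   # coverage bound is strict
        (60.0, 0.90, 0.80, False),
        (100.0, 1.0, 1.0, True),
    ],
)
def test_filter_boundaries(pident, qcov, scov, kept):
    hits = [make_hit(pident=pident, qcov=qcov, scov=scov, qlen=1000, slen=1000)]
    assert bool(filter_hits(hits)) is kept


def test_filter_idempotent_and_monotone():
    df = simulate_hits(30, 30, 30, seed=5)
    hits = read_frame(df)
    once = filter_hits(hits)
    assert filter_hits(once) == once
    for stricter in (
        ScreenConfig(min_pident=50.0),
        ScreenConfig(min_cov=0.9),
        ScreenConfig(min_pident=50.0, min_cov=0.9),
    ):
        assert len(filter_hits(hits, stricter)) <= len(once)


def read_frame(df: pd.DataFrame):
    return [
        HomologHit(
            query_id=r.qseqid, subject_id=r.sseqid, pident=r.pident,
            qstart=r.qstart, qend=r.qend, sstart=r.sstart, send=r.send,
            qlen=r.qlen, slen=r.slen,
        )
        for r in df.itertuples(index=False)
    ]


@given(st.integers(0, 2**31 - 1))
def test_filter_matches_naive_recheck(seed):
    """Per-row re-evaluation of the three predicates is the oracle."""
    rng = np.random.default_rng(seed)
    df = simulate_hits(int(rng.integers(0, 20)), int(rng.integers(0, 20)),
                       int(rng.integers(0, 20)), seed=seed)
    hits = read_frame(df)
    cfg = ScreenConfig()
    expected = [
        h for h in hits
        if h.pident >= cfg.min_pident
        and (h.qend - h.qstart + 1) / h.qlen > cfg.min_cov
        and (h.send - h.sstart + 1) / h.slen > cfg.min_cov
    ]
    assert filter_hits(hits, cfg) == expected


def test_organelle_drop_requires_located_in():
    hits = [make_hit(query="g1"), make_hit(query="g2"), make_hit(query="g3")]
    ann = pd.DataFrame(
        [
            ("g1", "located in", "Chloroplast"),   # case-insensitive term
            ("g2", "involved in", "chloroplast"),  # wrong relationship
        ],
        columns=["gene_id", "relationship_type", "term"],
    )
    kept, dropped = drop_organelle_genes(hits, ann)
    assert dropped == {"g1"}
    assert [h.query_id for h in kept] == ["g2", "g3"]


def test_organelle_malformed_annotation_rejected():
    ann = pd.DataFrame([("g1", "located in")], columns=["gene_id", "relationship_type"])
    with pytest.raises(ValueError):
        drop_organelle_genes([make_hit()], ann)


@pytest.mark.parametrize(
    "pident,flagged",
    [(76.0, False), (75.9, False), (76.1, True), (99.2, True)],
)
def test_contamination_guard_is_strict(pident, flagged):
    hits = [make_hit(pident=pident)]
    assert bool(flag_contamination(hits)) is flagged


def test_screen_end_to_end(tmp_path):
    df = simulate_hits(12, 20, 8, seed=11)
    hits_path = tmp_path / "hits.tsv"
    df.to_csv(hits_path, sep="\t", index=False, header=False)
    result = screen(hits_path)
    assert len(result.kept_hits) == 12
    assert result.plant_genes == {h.query_id for h in result.kept_hits}
    assert result.bacterial_proteins == {h.subject_id for h in result.kept_hits}
    assert result.contamination_flags == []


def test_screen_empty_table(tmp_path):
    hits_path = tmp_path / "hits.tsv"
    hits_path.write_text("")
    result = screen(hits_path)
    assert result.kept_hits == [] and result.plant_genes == set()


def test_screen_all_queries_organelle(tmp_path):
    df = simulate_hits(5, 0, 0, seed=2)
    hits_path = tmp_path / "hits.tsv"
    df.to_csv(hits_path, sep="\t", index=False, header=False)
    genes = sorted(set(df["qseqid"]))
    ann = simulate_organelle_annotations(genes, genes, seed=2)
    ann_path = tmp_path / "ann.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    result = screen(hits_path, ann_path)
    assert result.plant_genes == set()
    assert result.dropped_organelle == set(genes)


def test_read_hits_round_trip(tmp_path):
    df = simulate_hits(4, 2, 2, seed=9)
    path = tmp_path / "hits.tsv"
    df.to_csv(path, sep="\t", index=False, header=False)
    hits = read_hits(path)
    assert len(hits) == 8
    assert {h.query_id for h in hits} == set(df["qseqid"])
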