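"""Shard routing and the sharding-transparency property."""

import random

import pytest

from seqindex.errors import ShardUnreachableError
from seqindex.index import Index
from seqindex.shards import LocalShard, ShardSet, route_document


class TestRouting:
    def test_single_shard_always_zero(self):
        assert all(route_document(f"d{i}", 1) == 0 for i in range(50))

    def test_deterministic(self):
        assert route_document("SYN0001", 3) == route_document("SYN0001", 3)

    def test_balance_over_1000_ids(self):
        counts = [0, 0, 0]
        for i in range(1000):
            counts[route_document(f"doc-{i}", 3)] += 1
        assert min(counts) >= 200  # tolerance of the balance sanity check


def _partition(docs, n_shards, seed, schema):
    rng = random.Random(seed)
    ixs = [Index(schema=schema) for _ in range(n_shards)]
    for doc in docs:
        ixs[rng.randrange(n_shards)].add_document(doc)
    for ix in ixs:
        ix.commit()
    return ShardSet([LocalShard(ix) for ix in ixs], schema=schema)


class TestTransparency:
    """Distributed search must be indistinguishable from a single index."""

    @pytest.mark.parametrize("n_shards", [2, 3, 4])
    def test_random_partition_matches_single_index(
            self, n_shards, gff_index, gff_docs, oracle_queries, schema):
        shardset = _partition(gff_docs, n_shards, seed=n_shards, schema=schema)
        for q in oracle_queries:
            single = gff_index.search(q, 0, 25)
            dist = shardset.search(q, 0, 25)
            assert dist.total == single.total, q
            assert [h.doc_id for h in dist.hits] == \
                   [h.doc_id for h in single.hits], q
            for a, b in zip(single.hits, dist.hits):
                assert abs(a.score - b.score) <= 1e-9, (q, a.doc_id)

    def test_empty_query_results_from_every_decomposition(self, gff_docs, schema):
        shardset = _partition(gff_docs, 3, seed=1, schema=schema)
        res = shardset.search("type:nonexistenttoken", 0, 10)
        assert res.total == 0 and res.hits == []

    def test_offset_beyond_total(self, gff_docs, schema):
        shardset = _partition(gff_docs, 2, seed=2, schema=schema)
        total = shardset.search("type:gene", 0, 0).total
        res = shardset.search("type:gene", total + 10, 5)
        assert res.hits == [] and res.total == total

    def test_adding_empty_shard_changes_nothing(self, gff_docs, schema,
                                                oracle_queries):
        base = _partition(gff_docs, 2, seed=5, schema=schema)
        empty = Index(schema=schema)
        empty.commit()
        wider = ShardSet(list(base.shards) + [LocalShard(empty)], schema=schema)
        for q in oracle_queries[:30]:
            a, b = base.search(q, 0, 15), wider.search(q, 0, 15)
            assert a.total == b.total
            assert [(h.doc_id, h.score) for h in a.hits] == \
                   [(h.doc_id, h.score) for h in b.hits]


class TestFailurePolicy:
    def test_unreachable_shard_fails_loudly_naming_it(self, tmp_path):
        missing = str(tmp_path / "never-created")
        shardset = ShardSet([LocalShard(missing)])
        with pytest.raises(ShardUnreachableError) as exc:
            shardset.search("anything", 0, 5)
        assert "never-created" in str(exc.value)


class TestRemoteShard:
    def test_mixed_local_and_http_shard_matches_single_index(
            self, gff_index, gff_docs, schema, oracle_queries):
        """One shard behind a live service instance, one in-process."""
        import threading
        from seqindex.chunks import ChunkStore
        from seqindex.service import Service, serve
        from seqindex.shards import RemoteShard

        rng = random.Random(41)
        a, b = Index(schema=schema), Index(schema=schema)
        for doc in gff_docs:
            (a if rng.random() < 0.5 else b).add_document(doc)
        a.commit()
        b.commit()
        svc = Service(ShardSet([LocalShard(b)], schema=schema), ChunkStore())
        httpd = serve(svc, "127.0.0.1", 0)
        threading.Thread(target=httpd.serve_forever, daemon=True).start()
        url = f"http://127.0.0.1:{httpd.server_address[1]}"
        try:
            mixed = ShardSet([LocalShard(a), RemoteShard(url)], schema=schema)
            for q in oracle_queries[:25]:
                single = gff_index.search(q, 0, 10)
                dist = mixed.search(q, 0, 10)
                assert dist.total == single.total, q
                assert [h.doc_id for h in dist.hits] == \
                       [h.doc_id for h in single.hits], q
                for x, y in zip(single.hits, dist.hits):
                    assert abs(x.score - y.score) <= 1e-9, q
        finally:
            httpd.shutdown()

    def test_unreachable_http_shard_fails_loudly(self):
        from seqindex.shards import RemoteShard
        dead = RemoteShard("http://127.0.0.1:9", timeout=0.5)
        shardset = ShardSet([dead])
        with pytest.raises(ShardUnreachableError) as exc:
            shardset.search("x", 0, 5)
        assert "127.0.0.1:9" in str(exc.value)
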