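import pytest

import invrep as iv


class GridRuns:
    """Memoized searches over the default verification grid.

    Indexes are built once per sequence and per-centre mismatch discovery is
    shared across parameter sets, so the grid-wide property checks can reuse
    each other's work.
    """

    def __init__(self) -> None:
        self.sequences = iv.ci_fixture_sequences()
        self.params = iv.ci_parameter_grid()
        self._indexes: dict[str, iv.IndexedSequence] = {}
        self._caches: dict[tuple[str, str], dict] = {}
        self._fast: dict[tuple[str, iv.SearchParams], list] = {}

    def index(self, seq: iv.DegenerateSequence) -> iv.IndexedSequence:
        if seq.name not in self._indexes:
            self._indexes[seq.name] = iv.IndexedSequence(seq)
        return self._indexes[seq.name]

    def fast(self, seq: iv.DegenerateSequence, params: iv.SearchParams) -> list:
        key = (seq.name, params)
        if key not in self._fast:
            cache = self._caches.setdefault((seq.name, params.scheme), {})
            self._fast[key] = iv.find_inverted_repeats(
                seq, params, index=self.index(seq), mismatch_cache=cache
            )
        return self._fast[key]


@pytest.fixture(scope="session")
def grid_runs() -> GridRuns:
    return GridRuns()
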