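"""Aho-Corasick multi-pattern string matching.

Classic goto/failure/output automaton: build a trie over the patterns, then
BFS to wire failure links (longest proper suffix that is also a trie prefix)
and merge output sets along them.  One pass over a text of length n yields
every occurrence of every pattern in O(n + matches), independent of the
dictionary size — which is what makes scanning millions of metadata strings
against tens of thousands of ontology surface forms practical.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator


class AhoCorasick:
    """Automaton over a fixed set of patterns.

    Patterns are matched verbatim (no case folding here; callers normalize).
    Duplicate patterns are stored once.
    """

    def __init__(self, patterns: Iterable[str]):
        self.patterns: list[str] = []
        seen: dict[str, int] = {}
        # trie: list of dicts char -> state; output: pattern indices per state
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]
        for pat in patterns:
            if not pat or pat in seen:
                continue
            seen[pat] = len(self.patterns)
            self.patterns.append(pat)
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[state][ch] = nxt
                    self._goto.append({})
                    self._out.append([])
                state = nxt
            self._out[state].append(seen[pat])
        self._fail = self._build_failure_links()

    def _build_failure_links(self) -> list[int]:
        fail = [0] * len(self._goto)
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = fail[state]
                while f and ch not in self._goto[f]:
                    f = fail[f]
                fail[nxt] = self._goto[f].get(ch, 0)
                if fail[nxt] == nxt:
                    fail[nxt] = 0
                self._out[nxt].extend(self._out[fail[nxt]])
        return fail

    def finditer(self, text: str) -> Iterator[tuple[int, int, str]]:
        """Yield ``(start, end_exclusive, pattern)`` for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for idx in self._out[state]:
                pat = self.patterns[idx]
                yield i - len(pat) + 1, i + 1, pat

    def __len__(self) -> int:
        return len(self.patterns)
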