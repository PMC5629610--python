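"""Porter stemming, self-contained.

The classic Porter (1980) algorithm, implemented from the published
definition.  Only lowercase alphabetic input is expected; anything of
length <= 2 or containing non-letters is returned unchanged.
"""

from __future__ import annotations

__all__ = ["porter_stem", "stem_tokens"]

_VOWELS = "aeiou"


class _Porter:
    """Mutable buffer ``b[0:k+1]`` holds the current stem."""

    def __init__(self, word: str) -> None:
        self.b = word
        self.k = len(word) - 1
        self.j = 0

    def cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self.cons(i - 1)
        return True

    def m(self) -> int:
        """Number of consonant-vowel sequences in b[0:j+1]."""
        n = 0
        i = 0
        while True:
            if i > self.j:
                return n
            if not self.cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self.cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self.cons(i):
                    break
                i += 1
            i += 1

    def vowel_in_stem(self) -> bool:
        return any(not self.cons(i) for i in range(self.j + 1))

    def double_c(self, j: int) -> bool:
        return j >= 1 and self.b[j] == self.b[j - 1] and self.cons(j)

    def cvc(self, i: int) -> bool:
        if i < 2 or not self.cons(i) or self.cons(i - 1) or not self.cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    def ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1:
            return False
        if self.b[self.k - length + 1 : self.k + 1] != s:
            return False
        self.j = self.k - length
        return True

    def set_to(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s
        self.k = len(self.b) - 1

    def r(self, s: str) -> None:
        if self.m() > 0:
            self.set_to(s)

    def step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self.ends("sses"):
                self.k -= 2
            elif self.ends("ies"):
                self.set_to("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self.ends("eed"):
            if self.m() > 0:
                self.k -= 1
        elif (self.ends("ed") or self.ends("ing")) and self.vowel_in_stem():
            self.k = self.j
            if self.ends("at"):
                self.set_to("ate")
            elif self.ends("bl"):
                self.set_to("ble")
            elif self.ends("iz"):
                self.set_to("ize")
            elif self.double_c(self.k):
                self.k -= 1
                if self.b[self.k] in "lsz":
                    self.k += 1
            elif self.m() == 1 and self.cvc(self.k):
                self.set_to("e")

    def step1c(self) -> None:
        if self.ends("y") and self.vowel_in_stem():
            self.b = self.b[: self.k] + "i"

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
        ("logi", "log"),
    ]

    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]

    def _map_suffixes(self, table: list[tuple[str, str]]) -> None:
        for suffix, repl in sorted(table, key=lambda p: -len(p[0])):
            if self.ends(suffix):
                self.r(repl)
                return

    _STEP4 = [
        "ement", "ance", "ence", "able", "ible", "ment", "ant", "ent", "ion",
        "ism", "ate", "iti", "ous", "ive", "ize", "al", "er", "ic", "ou",
    ]

    def step4(self) -> None:
        for suffix in self._STEP4:
            if self.ends(suffix):
                if suffix == "ion" and (self.j < 0 or self.b[self.j] not in "st"):
                    continue
                if self.m() > 1:
                    self.k = self.j
                return

    def step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self.m()
            if a > 1 or (a == 1 and not self.cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self.double_c(self.k) and self.m() > 1:
            self.k -= 1

    def run(self) -> str:
        if self.k <= 1:
            return self.b
        self.step1ab()
        self.step1c()
        self._map_suffixes(self._STEP2)
        self._map_suffixes(self._STEP3)
        self.step4()
        self.step5()
        return self.b[: self.k + 1]


def porter_stem(word: str) -> str:
    """Stem a single lowercase word; non-alphabetic words pass through."""
    if len(word) <= 2 or not word.isalpha():
        return word
    return _Porter(word).run()


def stem_tokens(tokens: list[str]) -> list[str]:
    return [porter_stem(t) for t in tokens]
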