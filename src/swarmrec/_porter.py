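"""Porter's suffix-stripping stemmer for English.

Self-contained implementation of the classic 1980 algorithm (steps 1a-5b)
so that stemming does not depend on an external NLP toolkit being present.
Operates on lowercase alphabetic strings; inputs shorter than 3 characters
are returned unchanged.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


class PorterStemmer:
    """Stateless stemmer; ``stem(word)`` is the only public entry point."""

    def stem(self, word: str) -> str:
        if len(word) <= 2:
            return word
        word = self._step1ab(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5(word)
        return word

    # -- letter classification -------------------------------------------

    @staticmethod
    def _is_cons(word: str, i: int) -> bool:
        ch = word[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return i == 0 or not PorterStemmer._is_cons(word, i - 1)
        return True

    @classmethod
    def _measure(cls, stem: str) -> int:
        """Number of VC sequences in the [C](VC)^m[V] decomposition."""
        n = len(stem)
        i = 0
        while i < n and cls._is_cons(stem, i):
            i += 1
        m = 0
        while i < n:
            while i < n and not cls._is_cons(stem, i):
                i += 1
            if i >= n:
                break
            m += 1
            while i < n and cls._is_cons(stem, i):
                i += 1
        return m

    @classmethod
    def _has_vowel(cls, stem: str) -> bool:
        return any(not cls._is_cons(stem, i) for i in range(len(stem)))

    @classmethod
    def _ends_double_cons(cls, word: str) -> bool:
        return (
            len(word) >= 2
            and word[-1] == word[-2]
            and cls._is_cons(word, len(word) - 1)
        )

    @classmethod
    def _ends_cvc(cls, word: str) -> bool:
        if len(word) < 3:
            return False
        n = len(word)
        return (
            cls._is_cons(word, n - 3)
            and not cls._is_cons(word, n - 2)
            and cls._is_cons(word, n - 1)
            and word[-1] not in "wxy"
        )

    # -- steps ------------------------------------------------------------

    def _step1ab(self, w: str) -> str:
        if w.endswith("sses"):
            w = w[:-2]
        elif w.endswith("ies"):
            w = w[:-2]
        elif not w.endswith("ss") and w.endswith("s"):
            w = w[:-1]

        flag = False
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        elif w.endswith("ed") and self._has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w = w[:-3]
            flag = True

        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif self._ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif self._measure(w) == 1 and self._ends_cvc(w):
                w += "e"
        return w

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
            w = w[:-1] + "i"
        return w

    _STEP2 = (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
        ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
        ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
        ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
        ("biliti", "ble"),
    )

    _STEP3 = (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    )

    _STEP4 = (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive",
        "ize",
    )

    def _step2(self, w: str) -> str:
        for suf, rep in self._STEP2:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if self._measure(stem) > 0:
                    return stem + rep
                return w
        return w

    def _step3(self, w: str) -> str:
        for suf, rep in self._STEP3:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if self._measure(stem) > 0:
                    return stem + rep
                return w
        return w

    def _step4(self, w: str) -> str:
        for suf in self._STEP4:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if suf == "ion" and (not stem or stem[-1] not in "st"):
                    return w
                if self._measure(stem) > 1:
                    return stem
                return w
        return w

    def _step5(self, w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._ends_cvc(stem)):
                w = stem
        if self._ends_double_cons(w) and w.endswith("l") and self._measure(w) > 1:
            w = w[:-1]
        return w


_DEFAULT = PorterStemmer()


def porter_stem(word: str) -> str:
    return _DEFAULT.stem(word)
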