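"""Scene cache with LFU/LRU eviction and a pluggable provider.

Environmental archives are far too large to mirror, so scenes (one raster
tile at one timestamp) are materialized on demand by a *provider* — any
callable ``key -> payload`` — and retained under a capacity limit.  Two
eviction strategies are offered, matching the two policies a production
service might run: least-frequently-used (drop the least accessed scenes)
and least-recently-used.  Ties break deterministically by oldest access,
then lexicographic key.

The cache is transparent: annotations computed through any capacity or
strategy are identical to direct reads, only the provider call pattern
differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import FetchError, ValidationError
from .grid import Scene

STRATEGIES = ("least_frequently_used", "least_recently_used")


@dataclass(frozen=True)
class CachePolicy:
    """Capacity (max scenes; ``inf`` allowed) and eviction strategy."""

    capacity: float = math.inf
    strategy: str = "least_frequently_used"

    def __post_init__(self):
        if not self.capacity > 0:
            raise ValidationError("cache capacity must be positive")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown eviction strategy {self.strategy!r}")


class SceneCache:
    """In-memory scene store with access accounting and bounded size."""

    def __init__(self, policy: CachePolicy = CachePolicy(), retries: int = 2):
        self.policy = policy
        self.retries = int(retries)
        self._scenes: dict = {}
        self._clock = 0  # logical time; deterministic across runs
        self.hits = 0
        self.misses = 0

    def __len__(self):
        return len(self._scenes)

    def __contains__(self, key):
        return key in self._scenes

    @property
    def keys(self):
        return set(self._scenes)

    def _tick(self) -> int:
        self._clock += 1
        return self._clock

    def get_scene(self, key, provider) -> Scene:
        """Return the scene for ``key``, materializing it at most once.

        A hit bumps ``access_count`` and ``last_access`` without touching
        the provider; a miss invokes the provider (with retries), stores the
        scene, then evicts down to capacity.  Provider failure after all
        retries raises :class:`FetchError` carrying the key.
        """
        sc = self._scenes.get(key)
        if sc is not None:
            self.hits += 1
            sc.access_count += 1
            sc.last_access = self._tick()
            return sc
        self.misses += 1
        err = None
        for _ in range(self.retries + 1):
            try:
                payload = provider(key)
                break
            except Exception as exc:  # noqa: BLE001 - surfaced via FetchError
                err = exc
        else:
            raise FetchError(key, err)
        sc = Scene(key=key, payload=payload, access_count=1, last_access=self._tick())
        self._scenes[key] = sc
        self.evict_to_capacity()
        return sc

    def _eviction_order(self):
        if self.policy.strategy == "least_frequently_used":
            return sorted(self._scenes.values(),
                          key=lambda s: (s.access_count, s.last_access, s.key))
        return sorted(self._scenes.values(),
                      key=lambda s: (s.last_access, s.key))

    def evict_to_capacity(self):
        """Evict policy-minimal scenes until size <= capacity; returns the
        removed keys in eviction order."""
        removed = []
        if math.isinf(self.policy.capacity):
            return removed
        excess = len(self._scenes) - int(self.policy.capacity)
        if excess <= 0:
            return removed
        for sc in self._eviction_order()[:excess]:
            del self._scenes[sc.key]
            removed.append(sc.key)
        return removed

    def clear(self):
        self._scenes.clear()
        self.hits = self.misses = 0
        self._clock = 0

    def stats(self) -> dict:
        return {"size": len(self._scenes), "hits": self.hits, "misses": self.misses}


def variable_provider(var):
    """Provider closure materializing scenes straight from a GridVariable.

    Scene keys are ``(variable id, timestamp index, tile index)`` as produced
    by :meth:`GridVariable.scene_key`.
    """
    def provide(key):
        vid, t_index, tile_index = key
        if vid != var.id:
            raise KeyError(f"provider for {var.id!r} asked for {vid!r}")
        return var.scene_payload(t_index, tile_index)
    return provide
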