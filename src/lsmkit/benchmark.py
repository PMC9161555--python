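"""Process resource sampling during long acquisitions.

Informational only: records CPU time and resident memory of the current
process at a fixed interval (default 5 s) so long recordings can be
checked for monotonic memory growth or CPU saturation after the fact.
Reads /proc on Linux; falls back to os.times() only elsewhere.
"""

from __future__ import annotations

import os
import threading
import time
from dataclasses import dataclass
from typing import List


@dataclass
class ResourceSample:
    t: float          # s since monitor start
    cpu_s: float      # cumulative user+system CPU seconds
    rss_mb: float     # resident set size, MiB


def _rss_mb() -> float:
    try:
        with open("/proc/self/statm") as f:
            pages = int(f.read().split()[1])
        return pages * os.sysconf("SC_PAGE_SIZE") / (1024.0 * 1024.0)
    except (OSError, ValueError, IndexError):
        return float("nan")


class ResourceMonitor:
    """Samples CPU and memory in a background thread at a fixed interval."""

    def __init__(self, interval_s: float = 5.0):
        self.interval_s = interval_s
        self.samples: List[ResourceSample] = []
        self._stop = threading.Event()
        self._thread = None
        self._t0 = None

    def _sample(self):
        t = os.times()
        self.samples.append(
            ResourceSample(
                t=time.monotonic() - self._t0,
                cpu_s=t.user + t.system,
                rss_mb=_rss_mb(),
            )
        )

    def _run(self):
        while not self._stop.wait(self.interval_s):
            self._sample()

    def __enter__(self):
        self._t0 = time.monotonic()
        self._sample()
        self._thread = threading.Thread(target=self._run, name="lsm-monitor")
        self._thread.start()
        return self

    def __exit__(self, *exc):
        self._stop.set()
        self._thread.join()
        self._sample()
        return False
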