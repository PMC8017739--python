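"""Cheap global counters used to prove zero-decode guarantees in tests.

The counters record how often the expensive operations ran.  They exist so
that properties like "index construction never decompresses a frame" or
"the control-bit scanner performs no integer decoding" are measurable facts
rather than code-review claims.
"""

from dataclasses import dataclass, field


@dataclass
class Counters:
    decompress_calls: int = 0      # full or partial coordinate decompressions
    decodeints_calls: int = 0      # Python-level mixed-radix decodes
    skip_frame_calls: int = 0
    encode_calls: int = 0
    _extras: dict = field(default_factory=dict)

    def reset(self) -> None:
        self.decompress_calls = 0
        self.decodeints_calls = 0
        self.skip_frame_calls = 0
        self.encode_calls = 0
        self._extras.clear()


counters = Counters()
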