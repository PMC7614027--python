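"""Stream naming and subscription routing.

Every plug-in's output is a named *stream*.  Streams generated by source
(input) plug-ins are named ``'Input'`` — or ``'Input1'``, ``'Input2'``, ... when
several sources coexist, in pipeline order — regardless of the plug-in's own
name; every other plug-in's stream is named after the plug-in itself
(lowercased, non-alphanumerics stripped).  Processing plug-ins subscribe to
exactly one stream (default ``'Input'``) and one layer of it (default ``-1``,
the last layer), mirroring the ``--<plugin>_stream`` / ``--<plugin>_layer``
command-line options.

A frame that reaches a plug-in is always forwarded to the next plug-in in the
pipeline whether or not it is accepted; acceptance only decides whether the
frame is also queued for this plug-in's worker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence


class PluginLike(Protocol):
    display_name: str
    is_input: bool


def normalize_plugin_name(display_name: str) -> str:
    """Deterministic stream token for a plug-in display name.

    Lowercase, with everything but letters and digits stripped:
    ``"Python Algorithm" -> "pythonalgorithm"``.  Idempotent.
    """
    token = "".join(ch for ch in display_name.lower() if ch.isalnum())
    if not token:
        raise ValueError(f"plugin name {display_name!r} normalizes to an empty token")
    return token


@dataclass(frozen=True)
class Subscription:
    """What a processing plug-in listens to: one stream, one layer of it."""
    stream: str = "Input"
    layer: int = -1


@dataclass
class StreamRegistry:
    """Wiring of a pipeline: producer stream names and per-plugin subscriptions.

    Keys are plug-in identities (the objects themselves); values survive
    run-time re-subscription, which swaps the whole Subscription atomically so
    any frame sees either the old or the new (stream, layer) pair.
    """

    stream_names: dict[int, str] = field(default_factory=dict)
    subscriptions: dict[int, Subscription] = field(default_factory=dict)
    _plugins: list[PluginLike] = field(default_factory=list)

    def stream_of(self, plugin: PluginLike) -> str:
        return self.stream_names[id(plugin)]

    def subscription_of(self, plugin: PluginLike) -> Subscription:
        return self.subscriptions[id(plugin)]

    def resubscribe(self, plugin: PluginLike, stream: str | None = None,
                    layer: int | None = None) -> None:
        """Atomically change what ``plugin`` accepts; effective for the next frame."""
        sub = self.subscriptions[id(plugin)]
        if stream is not None:
            sub = replace(sub, stream=stream)
        if layer is not None:
            sub = replace(sub, layer=layer)
        self.subscriptions[id(plugin)] = sub

    @property
    def plugins(self) -> list[PluginLike]:
        return list(self._plugins)

    def producer_streams(self) -> list[str]:
        return [self.stream_names[id(p)] for p in self._plugins]


def assign_stream_names(plugins: Sequence[PluginLike]) -> StreamRegistry:
    """Name every plug-in's output stream and install default subscriptions.

    The first input plug-in produces ``'Input'``; the k-th subsequent input
    plug-in produces ``'Input<k>'``.  Non-input plug-ins produce a stream named
    after themselves; a name collision between two non-input plug-ins gets a
    deterministic ``-2``, ``-3``, ... suffix.  Every non-input plug-in starts
    subscribed to ``'Input'``, layer ``-1``.
    """
    registry = StreamRegistry()
    registry._plugins = list(plugins)
    n_inputs = 0
    seen: dict[str, int] = {}
    for plugin in plugins:
        if getattr(plugin, "is_input", False):
            name = "Input" if n_inputs == 0 else f"Input{n_inputs}"
            n_inputs += 1
        else:
            base = normalize_plugin_name(plugin.display_name)
            count = seen.get(base, 0) + 1
            seen[base] = count
            name = base if count == 1 else f"{base}-{count}"
            registry.subscriptions[id(plugin)] = Subscription()
        registry.stream_names[id(plugin)] = name
    return registry


def accepts_frame(registry: StreamRegistry, plugin: PluginLike, frame) -> bool:
    """True iff ``frame`` travels on the stream ``plugin`` is subscribed to.

    Pure predicate: the frame is forwarded downstream regardless of the result.
    Input plug-ins accept nothing (they only produce).
    """
    sub = registry.subscriptions.get(id(plugin))
    if sub is None:
        return False
    return frame.stream_name == sub.stream
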