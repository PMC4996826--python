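"""Leaf containers: lockable parameters and result bags.

A :class:`Parameter` holds one dimension of the parameter space: a default
value, an optional *exploration range* (the ordered values the parameter
takes across single runs), a lock flag and a type tag.  Once a parameter's
value has been read inside a run it locks itself, so a later accidental
mutation — notoriously hard to track down in long sweeps — fails loudly
instead of silently skewing results.  Unlocking is explicit and logged.

A :class:`Result` is a named bag of items produced by one single run or by
post-processing.  Results are deliberately less restrictive than
parameters: besides scalars, sequences and arrays they accept mappings and
tabular frames.
"""

from __future__ import annotations

import logging
from typing import Any, Iterator, Sequence

from .exceptions import (
    EmptyRangeError,
    HeterogeneousRangeError,
    LockedError,
    UnsupportedTypeError,
)
from .typetags import BUILTIN_REGISTRY, TypeTagRegistry

logger = logging.getLogger(__name__)

#: tags a Parameter may carry (mappings/frames are for results only)
_PARAMETER_BASE_TAGS = {
    "bool", "int", "float", "complex", "str", "npscalar", "array",
    "tuple", "list",
}


class BaseContainer:
    """Common leaf-node plumbing: identity, comment, annotations."""

    kind = "leaf"

    def __init__(self, full_name: str, comment: str = ""):
        self.full_name = full_name
        self.comment = comment
        self.annotations: dict[str, Any] = {}
        #: False for stubs created by a structure-level load
        self.data_loaded = True

    @property
    def name(self) -> str:
        return self.full_name.rsplit(".", 1)[-1]

    def __repr__(self):
        return f"<{type(self).__name__} {self.full_name!r}>"


class Parameter(BaseContainer):
    """A single named parameter: default value plus optional exploration range."""

    container_type = "parameter"

    def __init__(self, full_name: str, default: Any = None, comment: str = "",
                 registry: TypeTagRegistry | None = None):
        super().__init__(full_name, comment)
        self._registry = registry if registry is not None else BUILTIN_REGISTRY
        self.locked = False
        self.type_tag: str | None = None
        self._default: Any = None
        self._range: list[Any] | None = None
        #: set once runs over the current range completed; range may then
        #: only be appended to, never rewritten
        self._range_frozen = False
        if default is not None:
            self.set(default)

    # -- value -------------------------------------------------------------

    @property
    def default(self) -> Any:
        return self._default

    def set(self, value: Any) -> "Parameter":
        """Set the default value (rejects locked parameters and odd types)."""
        if self.locked:
            raise LockedError(
                f"parameter {self.full_name!r} is locked; unlock() it explicitly "
                f"before changing its value"
            )
        tag = self._registry.tag_for(value)  # raises UnsupportedTypeError
        if tag.split(":", 1)[0] not in _PARAMETER_BASE_TAGS:
            raise UnsupportedTypeError(
                f"values of tag {tag!r} are not allowed in parameters"
            )
        self._default = value
        self.type_tag = tag
        return self

    def lock(self) -> "Parameter":
        self.locked = True
        return self

    def unlock(self) -> "Parameter":
        if self.locked:
            logger.warning("unlocking parameter %s", self.full_name)
        self.locked = False
        return self

    # -- exploration range ---------------------------------------------------

    @property
    def range(self) -> list[Any] | None:
        return self._range

    @property
    def explored(self) -> bool:
        return self._range is not None

    def set_range(self, values: Sequence[Any]) -> "Parameter":
        """Install the exploration range (one homogeneous dimension)."""
        if self.locked:
            raise LockedError(f"parameter {self.full_name!r} is locked")
        if self._range_frozen:
            raise LockedError(
                f"runs over the range of {self.full_name!r} have completed; "
                f"the range can only be appended to (expand)"
            )
        self._range = list(self._check_range(values))
        return self

    def append_range(self, values: Sequence[Any]) -> "Parameter":
        """Append new explored points; the only range mutation allowed after runs."""
        checked = self._check_range(values)
        if self._range is None:
            self._range = list(checked)
        else:
            self._range.extend(checked)
        return self

    def _check_range(self, values: Sequence[Any]) -> Sequence[Any]:
        values = list(values)
        if not values:
            raise EmptyRangeError(
                f"exploration range for {self.full_name!r} is empty"
            )
        tags = []
        for v in values:
            try:
                tags.append(self._registry.tag_for(v))
            except UnsupportedTypeError as exc:
                raise HeterogeneousRangeError(str(exc)) from exc
        if len(set(tags)) != 1:
            raise HeterogeneousRangeError(
                f"range elements of {self.full_name!r} carry mixed type tags "
                f"{sorted(set(tags))}; one dimension holds one kind"
            )
        if self.type_tag is not None and tags[0] != self.type_tag:
            raise HeterogeneousRangeError(
                f"range tag {tags[0]!r} does not match default tag "
                f"{self.type_tag!r} of {self.full_name!r}"
            )
        if self.type_tag is None:
            self.type_tag = tags[0]
        return values

    def freeze_range(self) -> None:
        """Mark the current range as executed (called by the runner)."""
        self._range_frozen = True

    def value_at(self, run_index: int) -> Any:
        """Value for one run: ``range[run_index]`` if explored, else default."""
        if self._range is None:
            return self._default
        if not 0 <= run_index < len(self._range):
            raise IndexError(
                f"run index {run_index} out of bounds for range of length "
                f"{len(self._range)} ({self.full_name})"
            )
        return self._range[run_index]

    def __len__(self) -> int:
        return len(self._range) if self._range is not None else 0


class Result(BaseContainer):
    """A named bag of result items (item name → typed value)."""

    container_type = "result"

    def __init__(self, full_name: str, comment: str = "",
                 registry: TypeTagRegistry | None = None, **items: Any):
        super().__init__(full_name, comment)
        self._registry = registry if registry is not None else BUILTIN_REGISTRY
        self._items: dict[str, Any] = {}
        self._tags: dict[str, str] = {}
        for name, value in items.items():
            self.set(name, value)

    def set(self, name: str, value: Any) -> "Result":
        if not name.isidentifier():
            raise UnsupportedTypeError(
                f"result item name {name!r} is not a valid path component"
            )
        self._tags[name] = self._registry.tag_for(value)
        self._items[name] = value
        return self

    def get(self, name: str) -> Any:
        return self._items[name]

    def tag(self, name: str) -> str:
        return self._tags[name]

    @property
    def items_dict(self) -> dict[str, Any]:
        return dict(self._items)

    def __contains__(self, name: str) -> bool:
        return name in self._items

    def __iter__(self) -> Iterator[str]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __getattr__(self, name: str) -> Any:
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self.__dict__["_items"][name]
        except KeyError:
            raise AttributeError(
                f"result {self.full_name!r} has no item {name!r}"
            ) from None
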