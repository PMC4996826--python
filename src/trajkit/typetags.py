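"""Type tags and HDF5 value codecs.

Every value held by a parameter or result carries a *type tag*: a short
string recording the stored kind so that a round trip through HDF5 restores
exactly the original Python object — an ``int`` comes back as an ``int``,
a ``tuple`` stays tuple-like, a NumPy scalar keeps its dtype.

Tags have the form ``base`` or ``base:param`` (e.g. ``"float"``,
``"npscalar:int64"``, ``"tuple:str"``).  Codecs are looked up by the base
part.  Custom container kinds plug in through
:func:`register_container_kind`; a loader reading a file that contains an
unregistered tag raises :class:`~trajkit.exceptions.UnknownTagError` naming
the tag, so the registry plays the role of the dynamic-import list a loader
must be told about.

Supported out of the box: Python ``bool``/``int``/``float``/``complex``/
``str``; NumPy scalars; 1-D and 2-D NumPy arrays (numeric, boolean or
unicode text); homogeneous non-nested tuples and lists of scalars; and —
intended for results — string-keyed mappings and pandas DataFrames.
Nested or heterogeneous sequences are rejected.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .exceptions import DuplicateTagError, UnknownTagError, UnsupportedTypeError

#: datasets at or above this size get zlib compression (level 4)
COMPRESSION_THRESHOLD = 1024
_COMPRESSION = dict(compression="gzip", compression_opts=4)

_SCALAR_TAGS = {"bool", "int", "float", "complex", "str"}


def _maybe_compress(arr: np.ndarray) -> dict:
    return dict(_COMPRESSION) if arr.nbytes >= COMPRESSION_THRESHOLD else {}


class ValueCodec:
    """Encoder/decoder contract for one kind of value.

    Subclasses define :attr:`tag` (the base tag), recognise values via
    :meth:`matches`, and implement the HDF5 round trip.  ``decode`` must
    invert ``encode`` exactly, preserving the Python type.
    """

    tag: str = ""

    def matches(self, value: Any) -> bool:
        raise NotImplementedError

    def full_tag(self, value: Any) -> str:
        return self.tag

    def encode(self, group, name: str, value: Any) -> None:
        """Write ``value`` under ``group[name]``; caller sets the tag attr."""
        raise NotImplementedError

    def decode(self, group, name: str, tag: str) -> Any:
        raise NotImplementedError


class _BoolCodec(ValueCodec):
    tag = "bool"

    def matches(self, value):
        return isinstance(value, bool)

    def encode(self, group, name, value):
        group.create_dataset(name, data=np.bool_(value))

    def decode(self, group, name, tag):
        return bool(group[name][()])


class _IntCodec(ValueCodec):
    tag = "int"

    def matches(self, value):
        return isinstance(value, int) and not isinstance(value, bool)

    def encode(self, group, name, value):
        group.create_dataset(name, data=np.int64(value))

    def decode(self, group, name, tag):
        return int(group[name][()])


class _FloatCodec(ValueCodec):
    tag = "float"

    def matches(self, value):
        # np.float64 subclasses float; keep it for the npscalar codec
        return isinstance(value, float) and not isinstance(value, np.generic)

    def encode(self, group, name, value):
        group.create_dataset(name, data=np.float64(value))

    def decode(self, group, name, tag):
        return float(group[name][()])


class _ComplexCodec(ValueCodec):
    tag = "complex"

    def matches(self, value):
        return (isinstance(value, complex)
                and not isinstance(value, (bool, int, float))
                and not isinstance(value, np.generic))

    def encode(self, group, name, value):
        group.create_dataset(name, data=np.complex128(value))

    def decode(self, group, name, tag):
        return complex(group[name][()])


class _StrCodec(ValueCodec):
    tag = "str"

    def matches(self, value):
        return isinstance(value, str)

    def encode(self, group, name, value):
        group.create_dataset(name, data=value)

    def decode(self, group, name, tag):
        raw = group[name][()]
        return raw.decode("utf-8") if isinstance(raw, bytes) else str(raw)


class _NumpyScalarCodec(ValueCodec):
    """NumPy scalar of any numeric/bool dtype; dtype kept in the tag."""

    tag = "npscalar"

    def matches(self, value):
        return isinstance(value, np.generic) and not isinstance(value, np.str_)

    def full_tag(self, value):
        return f"npscalar:{value.dtype.name}"

    def encode(self, group, name, value):
        group.create_dataset(name, data=value)

    def decode(self, group, name, tag):
        dtype = tag.split(":", 1)[1]
        return np.dtype(dtype).type(group[name][()])


class _ArrayCodec(ValueCodec):
    """1-D/2-D NumPy array; numeric, boolean or unicode text dtype."""

    tag = "array"

    def matches(self, value):
        return (
            isinstance(value, np.ndarray)
            and value.ndim in (1, 2)
            and value.dtype.kind in "biufcU"
        )

    def encode(self, group, name, value):
        if value.dtype.kind == "U":
            import h5py

            ds = group.create_dataset(
                name, data=value.astype(object), dtype=h5py.string_dtype("utf-8")
            )
            ds.attrs["text_dtype"] = str(value.dtype)
        else:
            group.create_dataset(name, data=value, **_maybe_compress(value))

    def decode(self, group, name, tag):
        ds = group[name]
        if "text_dtype" in ds.attrs:
            raw = ds.asstr()[()]
            return np.asarray(raw, dtype=ds.attrs["text_dtype"])
        return ds[()]


def _scalar_tag(value: Any) -> str | None:
    if isinstance(value, np.generic):
        return None
    if isinstance(value, bool):
        return "bool"
    if isinstance(value, int):
        return "int"
    if isinstance(value, float):
        return "float"
    if isinstance(value, complex):
        return "complex"
    if isinstance(value, str):
        return "str"
    return None


class _SequenceCodec(ValueCodec):
    """Homogeneous, non-nested tuple or list of scalars (nonempty)."""

    pytype: type = tuple

    def matches(self, value):
        if not isinstance(value, self.pytype) or len(value) == 0:
            return False
        tags = {_scalar_tag(v) for v in value}
        return len(tags) == 1 and None not in tags

    def full_tag(self, value):
        return f"{self.tag}:{_scalar_tag(value[0])}"

    def encode(self, group, name, value):
        elem = _scalar_tag(value[0])
        if elem == "str":
            import h5py

            group.create_dataset(
                name, data=list(value), dtype=h5py.string_dtype("utf-8")
            )
        else:
            dtype = {"bool": np.bool_, "int": np.int64,
                     "float": np.float64, "complex": np.complex128}[elem]
            group.create_dataset(name, data=np.asarray(value, dtype=dtype))

    def decode(self, group, name, tag):
        elem = tag.split(":", 1)[1]
        ds = group[name]
        if elem == "str":
            vals = [v for v in ds.asstr()[()]]
        else:
            py = {"bool": bool, "int": int, "float": float, "complex": complex}[elem]
            vals = [py(v) for v in ds[()]]
        return self.pytype(vals)


class _TupleCodec(_SequenceCodec):
    tag = "tuple"
    pytype = tuple


class _ListCodec(_SequenceCodec):
    tag = "list"
    pytype = list


class _MappingCodec(ValueCodec):
    """String-keyed dict whose values are scalars or arrays (results only)."""

    tag = "mapping"

    def matches(self, value):
        return isinstance(value, dict) and all(
            isinstance(k, str) for k in value
        )

    def encode(self, group, name, value):
        sub = group.create_group(name)
        reg = BUILTIN_REGISTRY
        for k, v in value.items():
            reg.encode(sub, k, v)

    def decode(self, group, name, tag):
        sub = group[name]
        reg = BUILTIN_REGISTRY
        return {k: reg.decode(sub, k) for k in sub}


class _FrameCodec(ValueCodec):
    """pandas DataFrame stored as per-column datasets plus a column-order attr."""

    tag = "frame"

    def matches(self, value):
        return isinstance(value, pd.DataFrame)

    def encode(self, group, name, value):
        sub = group.create_group(name)
        sub.attrs["columns"] = [str(c) for c in value.columns]
        arr_codec = _ArrayCodec()
        for col in value.columns:
            arr = value[col].to_numpy()
            if arr.dtype.kind == "O":
                arr = arr.astype(str)
            arr_codec.encode(sub, str(col), arr)
        arr_codec.encode(sub, "__index__", value.index.to_numpy())

    def decode(self, group, name, tag):
        sub = group[name]
        arr_codec = _ArrayCodec()
        cols = list(sub.attrs["columns"])
        data = {c: arr_codec.decode(sub, c, "array") for c in cols}
        index = arr_codec.decode(sub, "__index__", "array")
        return pd.DataFrame(data, index=index, columns=cols)


class TypeTagRegistry:
    """Maps base tags to codecs; the loader's source of container constructors."""

    def __init__(self):
        self._codecs: dict[str, ValueCodec] = {}
        self._order: list[ValueCodec] = []

    def register(self, codec: ValueCodec) -> None:
        if codec.tag in self._codecs:
            raise DuplicateTagError(f"type tag {codec.tag!r} is already registered")
        self._codecs[codec.tag] = codec
        self._order.append(codec)

    def copy(self) -> "TypeTagRegistry":
        new = TypeTagRegistry()
        new._codecs = dict(self._codecs)
        new._order = list(self._order)
        return new

    def codec_for_value(self, value: Any) -> ValueCodec:
        for codec in self._order:
            if codec.matches(value):
                return codec
        raise UnsupportedTypeError(
            f"no registered type tag supports value of type "
            f"{type(value).__name__}: {value!r}"
        )

    def codec_for_tag(self, tag: str) -> ValueCodec:
        base = tag.split(":", 1)[0]
        try:
            return self._codecs[base]
        except KeyError:
            raise UnknownTagError(
                f"no codec registered for type tag {tag!r}; "
                f"pass a registry that knows this tag when loading"
            ) from None

    def tag_for(self, value: Any) -> str:
        return self.codec_for_value(value).full_tag(value)

    def supports(self, value: Any) -> bool:
        try:
            self.codec_for_value(value)
            return True
        except UnsupportedTypeError:
            return False

    # HDF5 round trip ------------------------------------------------------

    def encode(self, group, name: str, value: Any) -> None:
        codec = self.codec_for_value(value)
        codec.encode(group, name, value)
        group[name].attrs["type_tag"] = codec.full_tag(value)

    def decode(self, group, name: str) -> Any:
        tag = group[name].attrs["type_tag"]
        if isinstance(tag, bytes):
            tag = tag.decode()
        return self.codec_for_tag(tag).decode(group, name, tag)


def _make_builtin_registry() -> TypeTagRegistry:
    reg = TypeTagRegistry()
    for codec in (
        _BoolCodec(), _IntCodec(), _FloatCodec(), _ComplexCodec(), _StrCodec(),
        _NumpyScalarCodec(), _ArrayCodec(), _TupleCodec(), _ListCodec(),
        _MappingCodec(), _FrameCodec(),
    ):
        reg.register(codec)
    return reg


#: registry with all built-in codecs; shared default for store and load
BUILTIN_REGISTRY = _make_builtin_registry()


def register_container_kind(tag: str, codec: ValueCodec,
                            registry: TypeTagRegistry | None = None) -> TypeTagRegistry:
    """Register a custom value codec under ``tag``.

    Returns the registry the codec was added to (the shared built-in
    registry unless one is passed).  Loading a file that uses the tag
    requires the same registry to be handed to the loader.
    """
    codec.tag = tag
    reg = registry if registry is not None else BUILTIN_REGISTRY
    reg.register(codec)
    return reg
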