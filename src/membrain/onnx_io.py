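"""ONNX import/export for the U-net, via a built-in protobuf wire codec.

The exporter emits a standard ONNX ModelProto (opset 13) using the op
vocabulary the network needs — Conv, Relu, MaxPool, Resize (nearest 2x),
Concat, Softmax — with weights as raw-data float32 initializers, so the
file loads in any ONNX-speaking framework.  The importer parses the same
vocabulary and reconstructs a :class:`membrain.nn.UNet`: the architecture
is inferred structurally (pool count -> depth, first/last conv shapes ->
channels and classes), so models exported from other tools round-trip as
long as they follow the standard double-conv U-net topology.

Only the small, stable subset of the protobuf wire format that ONNX model
files use (varint and length-delimited fields) is implemented here.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .nn.unet import UNet, UNetConfig


class OnnxFormatError(ValueError):
    """Raised for files that are not parseable ONNX protobufs."""


class UnsupportedLayerError(ValueError):
    """Raised when a graph contains an op outside the supported set."""


# ---------------------------------------------------------------------------
# protobuf wire primitives
# ---------------------------------------------------------------------------

def _varint(v: int) -> bytes:
    out = bytearray()
    while True:
        b = v & 0x7F
        v >>= 7
        if v:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def _key(field: int, wtype: int) -> bytes:
    return _varint((field << 3) | wtype)


def fv(field: int, value: int) -> bytes:
    """varint field"""
    return _key(field, 0) + _varint(int(value))


def fb(field: int, data: bytes) -> bytes:
    """length-delimited field"""
    return _key(field, 2) + _varint(len(data)) + data


def fs(field: int, s: str) -> bytes:
    return fb(field, s.encode("utf-8"))


def _read_varint(buf: bytes, pos: int) -> tuple[int, int]:
    result = shift = 0
    while True:
        if pos >= len(buf):
            raise OnnxFormatError("truncated protobuf message (varint)")
        b = buf[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7
        if shift > 70:
            raise OnnxFormatError("malformed varint")


def _iter_fields(buf: bytes):
    """Yield (field_number, wire_type, value) triples of one message."""
    pos = 0
    while pos < len(buf):
        key, pos = _read_varint(buf, pos)
        field, wtype = key >> 3, key & 7
        if wtype == 0:
            val, pos = _read_varint(buf, pos)
        elif wtype == 2:
            ln, pos = _read_varint(buf, pos)
            if pos + ln > len(buf):
                raise OnnxFormatError("truncated protobuf message (bytes field)")
            val = buf[pos : pos + ln]
            pos += ln
        elif wtype == 5:
            if pos + 4 > len(buf):
                raise OnnxFormatError("truncated protobuf message (fixed32)")
            val = struct.unpack("<f", buf[pos : pos + 4])[0]
            pos += 4
        elif wtype == 1:
            if pos + 8 > len(buf):
                raise OnnxFormatError("truncated protobuf message (fixed64)")
            val = struct.unpack("<d", buf[pos : pos + 8])[0]
            pos += 8
        else:
            raise OnnxFormatError(f"unsupported protobuf wire type {wtype}")
        yield field, wtype, val


def _collect(buf: bytes) -> dict[int, list]:
    fields: dict[int, list] = {}
    for field, _, val in _iter_fields(buf):
        fields.setdefault(field, []).append(val)
    return fields


# ---------------------------------------------------------------------------
# ONNX message builders
# ---------------------------------------------------------------------------

_FLOAT, _INT64 = 1, 7
# AttributeProto.type enum
_AT_FLOAT, _AT_INT, _AT_STRING, _AT_INTS = 1, 2, 3, 7


def _tensor(name: str, arr: np.ndarray) -> bytes:
    arr = np.ascontiguousarray(arr)
    if arr.dtype == np.float32:
        dt = _FLOAT
    elif arr.dtype == np.int64:
        dt = _INT64
    else:
        raise UnsupportedLayerError(f"tensor dtype {arr.dtype} not supported")
    msg = b"".join(fv(1, d) for d in arr.shape)
    msg += fv(2, dt)
    msg += fs(8, name)
    msg += fb(9, arr.tobytes())  # raw_data, little-endian
    return msg


def _attr_ints(name: str, values) -> bytes:
    return fb(5, fs(1, name) + b"".join(fv(8, v) for v in values) + fv(20, _AT_INTS))


def _attr_int(name: str, value: int) -> bytes:
    return fb(5, fs(1, name) + fv(3, value) + fv(20, _AT_INT))


def _attr_str(name: str, value: str) -> bytes:
    return fb(5, fs(1, name) + fb(4, value.encode()) + fv(20, _AT_STRING))


def _node(op: str, inputs, outputs, name: str, attrs: bytes = b"") -> bytes:
    msg = b"".join(fs(1, i) for i in inputs)
    msg += b"".join(fs(2, o) for o in outputs)
    msg += fs(3, name) + fs(4, op) + attrs
    return fb(1, msg)  # GraphProto.node


def _value_info(name: str, dims) -> bytes:
    """dims entries: int -> dim_value, str -> dim_param."""
    shape = b"".join(
        fb(1, fv(1, d) if isinstance(d, int) else fs(2, d)) for d in dims
    )
    ttype = fv(1, _FLOAT) + fb(2, shape)  # elem_type + shape
    return fs(1, name) + fb(2, fb(1, ttype))  # name + TypeProto.tensor_type


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _conv_ops(name: str, x: str, y: str, kernel: int, with_relu: bool = True) -> bytes:
    pad = kernel // 2
    attrs = (
        _attr_ints("kernel_shape", [kernel, kernel])
        + _attr_ints("pads", [pad, pad, pad, pad])
        + _attr_ints("strides", [1, 1])
    )
    pre = f"{y}_conv" if with_relu else y
    out = _node("Conv", [x, f"{name}.w", f"{name}.b"], [pre], f"{name}", attrs)
    if with_relu:
        out += _node("Relu", [pre], [y], f"{name}_relu")
    return out


def export_onnx(model: UNet, path: Path | str) -> Path:
    """Serialise architecture + trained weights to an ONNX file."""
    cfg = model.config
    nodes = b""
    inits = [_tensor(n, a) for n, a in model.params.items()]
    inits.append(_tensor("up_scales", np.array([1, 1, 2, 2], dtype=np.float32)))

    x = "input"
    skips = {}
    for i in range(cfg.depth):
        nodes += _conv_ops(f"enc{i}.conv1", x, f"enc{i}_a", 3)
        nodes += _conv_ops(f"enc{i}.conv2", f"enc{i}_a", f"enc{i}_b", 3)
        skips[i] = f"enc{i}_b"
        attrs = _attr_ints("kernel_shape", [2, 2]) + _attr_ints("strides", [2, 2])
        nodes += _node("MaxPool", [f"enc{i}_b"], [f"pool{i}"], f"pool{i}", attrs)
        x = f"pool{i}"
    nodes += _conv_ops("bottleneck.conv1", x, "bott_a", 3)
    nodes += _conv_ops("bottleneck.conv2", "bott_a", "bott_b", 3)
    x = "bott_b"
    for i in reversed(range(cfg.depth)):
        attrs = (
            _attr_str("mode", "nearest")
            + _attr_str("nearest_mode", "floor")
            + _attr_str("coordinate_transformation_mode", "asymmetric")
        )
        nodes += _node("Resize", [x, "", "up_scales"], [f"up{i}"], f"up{i}", attrs)
        nodes += _node(
            "Concat", [f"up{i}", skips[i]], [f"cat{i}"], f"cat{i}", _attr_int("axis", 1)
        )
        nodes += _conv_ops(f"dec{i}.conv1", f"cat{i}", f"dec{i}_a", 3)
        nodes += _conv_ops(f"dec{i}.conv2", f"dec{i}_a", f"dec{i}_b", 3)
        x = f"dec{i}_b"
    nodes += _conv_ops("head", x, "logits", 1, with_relu=False)
    nodes += _node("Softmax", ["logits"], ["probabilities"], "softmax", _attr_int("axis", 1))

    graph = nodes
    graph += fs(2, "membrain_unet")
    graph += b"".join(fb(5, t) for t in inits)
    graph += fb(11, _value_info("input", ["N", cfg.in_channels, "H", "W"]))
    graph += fb(12, _value_info("probabilities", ["N", cfg.n_classes, "H", "W"]))

    model_msg = fv(1, 7)  # ir_version 7
    model_msg += fs(2, "membrain")
    model_msg += fb(7, graph)
    model_msg += fb(8, fs(1, "") + fv(2, 13))  # opset_import: default domain, 13

    out = Path(path)
    out.write_bytes(model_msg)
    return out


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

_SUPPORTED_OPS = {"Conv", "Relu", "MaxPool", "Resize", "Concat", "Softmax"}


def _parse_tensor(buf: bytes) -> tuple[str, np.ndarray]:
    fields = _collect(buf)
    dims = tuple(fields.get(1, []))
    dt = fields.get(2, [None])[0]
    name = fields.get(8, [b""])[0].decode()
    if dt == _FLOAT:
        dtype = np.float32
    elif dt == _INT64:
        dtype = np.int64
    else:
        raise OnnxFormatError(f"initializer {name!r} has unsupported data_type {dt}")
    if 9 in fields:  # raw_data
        arr = np.frombuffer(fields[9][0], dtype=np.dtype(dtype).newbyteorder("<"))
    elif dt == _FLOAT and 4 in fields:  # packed float_data
        arr = np.frombuffer(fields[4][0], dtype="<f4")
    elif dt == _INT64 and 7 in fields:
        vals, pos = [], 0
        data = fields[7][0]
        while pos < len(data):
            v, pos = _read_varint(data, pos)
            vals.append(v)
        arr = np.array(vals, dtype=np.int64)
    else:
        raise OnnxFormatError(f"initializer {name!r} carries no data")
    expected = int(np.prod(dims)) if dims else arr.size
    if arr.size != expected:
        raise OnnxFormatError(f"initializer {name!r}: data size does not match dims {dims}")
    return name, arr.reshape(dims).astype(dtype)


def _parse_node(buf: bytes) -> dict:
    fields = _collect(buf)
    return {
        "inputs": [b.decode() for b in fields.get(1, [])],
        "outputs": [b.decode() for b in fields.get(2, [])],
        "name": fields.get(3, [b""])[0].decode(),
        "op": fields.get(4, [b""])[0].decode(),
    }


def import_model(path: Path | str) -> UNet:
    """Load an ONNX 2D pixel classifier and rebuild it as a trainable UNet.

    The graph must follow the standard U-net pattern in the supported op
    vocabulary; anything else raises a descriptive error naming the
    offending op or structural mismatch.
    """
    p = Path(path)
    if not p.is_file():
        raise OnnxFormatError(f"no such model file: {p}")
    model_fields = _collect(p.read_bytes())
    if 7 not in model_fields:
        raise OnnxFormatError("file contains no graph; not an ONNX model?")
    graph_fields = _collect(model_fields[7][0])
    inits = dict(_parse_tensor(t) for t in graph_fields.get(5, []))
    nodes = [_parse_node(nb) for nb in graph_fields.get(1, [])]
    if not nodes:
        raise OnnxFormatError("model graph has no nodes")
    for nd in nodes:
        if nd["op"] not in _SUPPORTED_OPS:
            raise UnsupportedLayerError(
                f"unsupported layer {nd['op']!r} (node {nd['name']!r}); "
                f"supported ops: {sorted(_SUPPORTED_OPS)}"
            )

    conv_nodes = [nd for nd in nodes if nd["op"] == "Conv"]
    depth = sum(1 for nd in nodes if nd["op"] == "MaxPool")
    if depth < 1 or len(conv_nodes) != 4 * depth + 3:
        raise UnsupportedLayerError(
            f"graph is not a double-conv U-net: {len(conv_nodes)} convs for "
            f"{depth} pooling stages"
        )

    def conv_w(idx: int) -> np.ndarray:
        name = conv_nodes[idx]["inputs"][1]
        if name not in inits:
            raise OnnxFormatError(f"conv weight {name!r} missing from initializers")
        return inits[name]

    first_w, last_w = conv_w(0), conv_w(-1)
    if last_w.shape[2:] != (1, 1):
        raise UnsupportedLayerError("final conv is not a 1x1 classification head")
    cfg = UNetConfig(
        depth=depth,
        base_channels=int(first_w.shape[0]),
        n_classes=int(last_w.shape[0]),
        in_channels=int(first_w.shape[1]),
    )

    model = UNet(cfg)
    canonical = (
        [f"enc{i}.conv{j}" for i in range(depth) for j in (1, 2)]
        + ["bottleneck.conv1", "bottleneck.conv2"]
        + [f"dec{i}.conv{j}" for i in reversed(range(depth)) for j in (1, 2)]
        + ["head"]
    )
    for cname, nd in zip(canonical, conv_nodes):
        w = inits[nd["inputs"][1]].astype(np.float32)
        if len(nd["inputs"]) > 2 and nd["inputs"][2] in inits:
            b = inits[nd["inputs"][2]].astype(np.float32).ravel()
        else:
            b = np.zeros(w.shape[0], dtype=np.float32)
        model.params[f"{cname}.w"] = w
        model.params[f"{cname}.b"] = b

    # shape-check against a freshly built reference
    ref = UNet(cfg, np.random.default_rng(0))
    for k, v in ref.params.items():
        if k not in model.params or model.params[k].shape != v.shape:
            raise UnsupportedLayerError(
                f"graph structure incompatible with a U-net: parameter {k} "
                f"has shape {model.params.get(k, np.empty(0)).shape}, expected {v.shape}"
            )
    return model
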