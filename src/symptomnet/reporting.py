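"""Pipeline orchestration, network layout and publication-style outputs.

`run_pipeline` drives the whole analysis from a YAML-configurable
:class:`RunConfig`: item selection, binarization, network estimation,
bootstrap contrast inference, optional two-sample permutation comparison,
optional ordinal GGM replication, and a shared force-directed layout with
plots.  Every artifact written embeds the master seed and a hash of the
configuration so runs are attributable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import IsingNetwork, LikertMatrix
from .elasso import RegularizationConfig
from .errors import ConfigError
from .ggm import ordinal_contrast
from .inference import (
    BootstrapConfig,
    ContrastSpec,
    run_primary_hypothesis,
)
from .nct import network_comparison_test
from .preprocessing import (
    ItemCatalog,
    binarize,
    default_catalog,
    endorsement_frequencies,
    select_items,
)

__all__ = ["RunConfig", "spring_layout", "run_pipeline", "plot_network"]

log = logging.getLogger("symptomnet")


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    inputs: list[str]
    output_dir: str
    catalog_path: str | None = None
    probe: str = "WL"
    rlh_items: tuple[str, ...] = ("SB", "HL", "GU")
    rpa_items: tuple[str, ...] = ("LS", "LE", "NI")
    n_lambda: int = 100
    gamma: float = 0.25
    combine_rule: str = "AND"
    n_boot: int = 10_000
    ci_width: float = 0.975
    alpha_pairwise: float = 0.05 / 18
    run_nct: bool = True
    n_perm: int = 10_000
    run_ggm: bool = True
    ggm_gamma: float = 0.5
    ggm_correlation: str = "pearson"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        for p in self.inputs:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.catalog_path is not None and not Path(self.catalog_path).exists():
            raise ConfigError(f"catalog path does not exist: {self.catalog_path}")
        if not 1 <= len(self.inputs) <= 2:
            raise ConfigError("provide one or two input datasets")

    def digest(self) -> str:
        """Stable hash of the configuration (provenance stamp)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def contrast_spec(self) -> ContrastSpec:
        return ContrastSpec(self.probe, tuple(self.rlh_items), tuple(self.rpa_items))

    def reg_config(self) -> RegularizationConfig:
        return RegularizationConfig(
            n_lambda=self.n_lambda, gamma=self.gamma, combine_rule=self.combine_rule
        )

    def boot_config(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_boot=self.n_boot,
            ci_width=self.ci_width,
            alpha_pairwise=self.alpha_pairwise,
            seed=self.seed,
        )


def spring_layout(
    networks: IsingNetwork | list[IsingNetwork], seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Force-directed (Fruchterman-Reingold) coordinates on mean weights.

    With two networks the layout is computed once on the element-wise mean
    of the weight matrices so both plots share identical node positions;
    absolute weights act as attraction.  Deterministic given the seed.
    """
    nets = [networks] if isinstance(networks, IsingNetwork) else list(networks)
    codes = nets[0].item_codes
    for net in nets[1:]:
        if net.item_codes != codes:
            raise ConfigError("all networks must share the same item set")
    mean_w = np.mean([np.abs(n.weights) for n in nets], axis=0)
    G = nx.Graph()
    G.add_nodes_from(codes)
    p = len(codes)
    for i in range(p):
        for j in range(i + 1, p):
            if mean_w[i, j] > 0:
                G.add_edge(codes[i], codes[j], weight=float(mean_w[i, j]))
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    return {c: (float(x), float(y)) for c, (x, y) in pos.items()}


def plot_network(
    network: IsingNetwork,
    coords: dict[str, tuple[float, float]],
    path: str | Path,
    spec: ContrastSpec | None = None,
    max_weight: float | None = None,
) -> None:
    """Draw the network with role-colored nodes and weight-scaled edges."""
    spec = spec or ContrastSpec()
    roles = {}
    for c in network.item_codes:
        if c == spec.probe:
            roles[c] = "#e377c2"  # probe
        elif c in spec.rlh_items:
            roles[c] = "#ffdd57"  # helplessness cluster
        elif c in spec.rpa_items:
            roles[c] = "#6abf69"  # positive-affect cluster
        else:
            roles[c] = "#bbbbbb"
    ref = max_weight or max(np.abs(network.weights).max(), 1e-9)
    fig, ax = plt.subplots(figsize=(6, 6))
    p = network.n_items
    for i in range(p):
        for j in range(i + 1, p):
            w = network.weights[i, j]
            if w == 0:
                continue
            a, b = network.item_codes[i], network.item_codes[j]
            ax.plot(
                [coords[a][0], coords[b][0]],
                [coords[a][1], coords[b][1]],
                color="#1f77b4",
                alpha=min(1.0, 0.15 + 0.85 * abs(w) / ref),
                linewidth=0.5 + 3.0 * abs(w) / ref,
                zorder=1,
            )
    for c in network.item_codes:
        x, y = coords[c]
        ax.scatter([x], [y], s=600, color=roles[c], edgecolor="k", zorder=2)
        ax.annotate(c, (x, y), ha="center", va="center", fontsize=8, zorder=3)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _stamped_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a bundle with the estimated networks, contrast tables and
    (when applicable) comparison results; writes all declared artifacts
    under ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.digest()} seed={config.seed}"

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    log.info("starting pipeline: %s", stamp)

    try:
        catalog = (
            ItemCatalog.from_file(config.catalog_path)
            if config.catalog_path
            else default_catalog()
        )
        spec = config.contrast_spec()
        reg = config.reg_config()
        boot = config.boot_config()

        bundle: dict = {"config_hash": config.digest(), "seed": config.seed}
        networks = []
        likerts = []
        for d, path in enumerate(config.inputs, start=1):
            name = f"dataset{d}"
            log.info("[%s] loading %s", name, path)
            try:
                likert = select_items(LikertMatrix.from_csv(path), catalog)
            except Exception as exc:
                raise type(exc)(f"[stage: load/{name}] {exc}") from exc
            likerts.append(likert)
            binary = binarize(likert)
            _stamped_csv(
                endorsement_frequencies(binary).T.reset_index(names="item"),
                outdir / f"{name}_endorsement.csv",
                stamp,
            )
            log.info("[%s] estimating network and bootstrap (n_boot=%d)",
                     name, boot.n_boot)
            try:
                result = run_primary_hypothesis(binary, spec, reg, boot)
            except Exception as exc:
                raise type(exc)(f"[stage: estimate/{name}] {exc}") from exc
            networks.append(result.network)
            result.network.to_json(
                outdir / f"{name}_network.json",
                config_hash=config.digest(),
                seed=config.seed,
            )
            _stamped_csv(result.network.edge_list(), outdir / f"{name}_edges.csv", stamp)
            table = result.to_frame()
            table["observed"] = table["observed"].round(2)
            table[["ci_lower", "ci_upper"]] = table[["ci_lower", "ci_upper"]].round(2)
            _stamped_csv(table, outdir / f"{name}_contrast_table.csv", stamp)
            full = result.to_frame()
            full_payload = full.to_dict(orient="records")
            (outdir / f"{name}_contrast_table.json").write_text(
                json.dumps(
                    {"config_hash": config.digest(), "seed": config.seed,
                     "rows": full_payload},
                    indent=2,
                )
            )
            bundle[name] = result

        if len(config.inputs) == 2 and config.run_nct:
            log.info("running permutation comparison (n_perm=%d)", config.n_perm)
            try:
                nct_result = network_comparison_test(
                    binarize(likerts[0]),
                    binarize(likerts[1]),
                    reg,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
            except Exception as exc:
                raise type(exc)(f"[stage: nct] {exc}") from exc
            nct_result.to_json(outdir / "nct.json")
            _stamped_csv(nct_result.edge_table, outdir / "nct_edges.csv", stamp)
            bundle["nct"] = nct_result

        if config.run_ggm:
            log.info("running ordinal GGM replication")
            try:
                groups = {f"dataset{d+1}": lik for d, lik in enumerate(likerts)}
                ggm_result = ordinal_contrast(
                    groups, spec, gamma=config.ggm_gamma,
                    method=config.ggm_correlation,
                )
            except Exception as exc:
                raise type(exc)(f"[stage: ggm] {exc}") from exc
            payload = {
                "config_hash": config.digest(),
                "seed": config.seed,
                "correlation_method": ggm_result["correlation_method"],
                "gamma": ggm_result["gamma"],
                "groups": {
                    k: {kk: vv for kk, vv in v.items() if kk != "network"}
                    for k, v in ggm_result["groups"].items()
                },
            }
            if "delta_difference" in ggm_result:
                payload["delta_difference"] = ggm_result["delta_difference"]
            (outdir / "ggm_contrast.json").write_text(json.dumps(payload, indent=2))
            bundle["ggm"] = ggm_result

        coords = spring_layout(networks, seed=config.seed)
        coord_df = pd.DataFrame(
            [(c, x, y) for c, (x, y) in coords.items()],
            columns=["item", "x", "y"],
        )
        _stamped_csv(coord_df, outdir / "layout.csv", stamp)
        ref = max(float(np.abs(n.weights).max()) for n in networks)
        for d, net in enumerate(networks, start=1):
            plot_network(net, coords, outdir / f"dataset{d}_network.png", spec,
                         max_weight=ref)
        bundle["layout"] = coords
        log.info("pipeline complete")
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()
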