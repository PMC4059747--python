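"""End-to-end processing chain: raw pings + logbook -> pressure indicators.

Convenience orchestration of the individual modules in their documented
order (clean, cut, interpolate, enrich, discover/classify métiers, match,
predict, mark fishing, grid, indicators).  Each step is also usable on
its own; this module exists for scripted runs and scoring against the
synthetic generator's truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import cleaning, effort, enrich, linkage, metier, tracks as tracks_mod


@dataclass
class PipelineResult:
    tally: dict
    tracks: list
    interp_tracks: list
    model: object
    silhouette_profile: list
    record_labels: list
    match_result: object
    ann_accuracy: float | None
    fishing_counts: dict
    grid: object
    indicator5_km2: float
    indicator6_km2: float

    @property
    def interp_pings(self):
        return [p for tr in self.interp_tracks for p in tr.pings]


def run_pipeline(sim, freq_min: float = 10.0, max_gap_h: float = 12.0,
                 k_range=range(2, 7), n_samples: int = 5, sample_size: int = 500,
                 grid_cell_deg: float = 0.1, seed: int = 0) -> PipelineResult:
    """Run the full chain on a :class:`~vmstrack.synthetic.SimulationResult`.

    Métier thresholds for fishing-point marking are taken from the
    scenario's specs after the discovered medoids are identified against
    the scenario's reference catch profiles (the automated analogue of the
    manual métier-editing step).
    """
    kept, tally = cleaning.clean_pipeline(sim.pings, harbours=sim.harbours,
                                          coastline=sim.coastline)
    cut, n_discarded = tracks_mod.cut_tracks(kept, max_gap_h=max_gap_h)
    tally["tracks detected"] = len(cut)
    tally["short tracks discarded"] = n_discarded
    for tr in cut:
        tracks_mod.infer_harbours(tr, sim.harbours)

    interp, n_skipped = tracks_mod.interpolate_tracks(cut, freq_min)
    all_pings = [p for tr in interp for p in tr.pings]
    tally["pings outside bathymetry"] = enrich.assign_depth(all_pings, sim.bathy)
    tally["tracks outside areas"] = enrich.assign_area(interp, sim.areas)

    model, profile = metier.discover_metiers(
        sim.logbook, k_range, n_samples=n_samples, sample_size=sample_size,
        seed=seed)
    references = {m.name: m.alpha for m in sim.scenario.metiers}
    model = metier.label_medoids(model, references)
    _, hard, _ = metier.classify(sim.logbook, model)
    for rec, lab in zip(sim.logbook, hard):
        rec.metier = lab

    match_result = linkage.match(interp, sim.logbook)
    labelled = [tr for tr in interp if tr.metier is not None]
    unlabelled = [tr for tr in interp if tr.metier is None]
    ann_acc = None
    if unlabelled and len({tr.metier for tr in labelled}) >= 2:
        _, _, ann_acc = linkage.predict_metier(labelled, unlabelled, seed=seed)

    fishing_counts = linkage.mark_fishing(all_pings, sim.thresholds, sim.harbours)

    from .effort import RegularGridSpec
    spec = RegularGridSpec(lon_min=8.0, lat_min=42.0, lon_max=10.0, lat_max=44.0,
                           cell_deg=grid_cell_deg)
    grid = effort.grid_effort(all_pings, spec, interval_min=freq_min)
    ind5 = effort.dcf_indicator5(grid)
    ind6 = effort.dcf_indicator6(grid) if grid.total_effort_h > 0 else 0.0

    return PipelineResult(tally=tally, tracks=cut, interp_tracks=interp,
                          model=model, silhouette_profile=profile,
                          record_labels=hard, match_result=match_result,
                          ann_accuracy=ann_acc, fishing_counts=fishing_counts,
                          grid=grid, indicator5_km2=ind5, indicator6_km2=ind6)
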