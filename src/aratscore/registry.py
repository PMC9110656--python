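"""Task registry for the Action Research Arm Test (ARAT).

The ARAT comprises 19 movement tasks grouped into four domains — grasp,
grip, pinch and gross movements — each rated on an ordinal 0-3 scale, for
a maximum total of 57 points per arm.  The instrument itself does not fix
a canonical machine-readable task list, so the registry below names tasks
by their domain and a 1-based within-domain index; the per-domain split
(grasp 6, grip 4, pinch 6, gross 3) is configurable but the total must
stay at 19.
"""

from __future__ import annotations

from dataclasses import dataclass

DOMAINS: tuple[str, ...] = ("grasp", "grip", "pinch", "gross")

#: tasks per domain; sums to 19
DEFAULT_DOMAIN_COUNTS: dict[str, int] = {"grasp": 6, "grip": 4, "pinch": 6, "gross": 3}

MAX_TASK_SCORE = 3
N_TASKS = 19
MAX_TOTAL_SCORE = N_TASKS * MAX_TASK_SCORE  # 57

#: clinical interpretation thresholds for the ARAT total score (points),
#: used only for annotating reports
MDC_POINTS = 3.5
MCID_POINTS_RANGE = (12, 17)

ARMS: tuple[str, ...] = ("more_affected", "less_affected")


@dataclass(frozen=True)
class TaskInfo:
    """One ARAT task: global 1-based index, domain, index within domain."""

    task: int
    domain: str
    domain_task: int


def build_task_registry(
    domain_counts: dict[str, int] | None = None,
) -> list[TaskInfo]:
    """Return the ordered list of 19 ARAT tasks.

    Parameters
    ----------
    domain_counts
        Tasks per domain.  Must cover exactly the four ARAT domains and
        sum to 19.
    """
    counts = dict(DEFAULT_DOMAIN_COUNTS if domain_counts is None else domain_counts)
    if set(counts) != set(DOMAINS):
        raise ValueError(f"domain_counts must have exactly the domains {DOMAINS}")
    if any(c < 1 for c in counts.values()):
        raise ValueError("every domain needs at least one task")
    total = sum(counts.values())
    if total != N_TASKS:
        raise ValueError(f"task counts must sum to {N_TASKS}, got {total}")
    registry: list[TaskInfo] = []
    task = 1
    for domain in DOMAINS:
        for j in range(1, counts[domain] + 1):
            registry.append(TaskInfo(task=task, domain=domain, domain_task=j))
            task += 1
    return registry


TASK_REGISTRY: list[TaskInfo] = build_task_registry()

#: task index (1-19) -> domain, for the default registry
TASK_DOMAIN: dict[int, str] = {t.task: t.domain for t in TASK_REGISTRY}
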