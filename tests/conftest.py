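from datetime import datetime

import pytest

from phitkit import EngineContext, Scheduler, TaskEntry
from phitkit.fixtures import write_fixture_app

DEMO_TASKS = ("sleep%environment", "mindfulness%bodyScan", "PSQI")


def make_ctx(now=None, **kwargs) -> EngineContext:
    return EngineContext(now=now or datetime(2024, 3, 10, 14, 0), **kwargs)


def make_scheduler(task_ids=DEMO_TASKS) -> Scheduler:
    scheduler = Scheduler()
    for i, task_id in enumerate(task_ids):
        scheduler.add_task(TaskEntry(task_id=task_id, title=task_id,
                                     menu_index=i))
    return scheduler


@pytest.fixture
def ctx() -> EngineContext:
    return make_ctx()


@pytest.fixture
def advisor_ctx() -> EngineContext:
    return make_ctx(scheduler=make_scheduler())


@pytest.fixture(scope="session")
def fixture_app(tmp_path_factory):
    """The demo two-protocol study bundle, written once per session."""
    base = tmp_path_factory.mktemp("app")
    return write_fixture_app(base)
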