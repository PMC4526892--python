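"""Lexer, parser, and evaluator semantics of the logic language."""
from datetime import datetime
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from phitkit import (ConfigError, EngineContext, LexError, LogicParseError,
                     RuntimeLogicError, Value, coerce_compare, evaluate,
                     execute, interpolate, parse_logic, tokenize, unparse)
from phitkit.logic import ast
from phitkit.fixtures import (NESTED_WHILE_LOGIC, PTHX_STATUS_LOGIC,
                              SLEEP_ADVISOR_XML, STATEMENT_SNIPPETS,
                              USERHX_VALIDATION_LOGIC)
from phitkit.logic.builtins import default_registry

from conftest import make_ctx, make_scheduler


# --- tokenizer ------------------------------------------------------------

def test_tokenize_set_statement():
    kinds = [(t.kind, t.value) for t in tokenize('set {ptHx_age} = "15";')]
    assert kinds == [("keyword", "set"), ("varref", "ptHx_age"),
                     ("op", "="), ("string", "15"), ("punct", ";")]


def test_tokenize_typographic_quotes_normalized():
    tokens = tokenize('set {ptHx_age} = “15”;')
    assert [t.value for t in tokens if t.kind == "string"] == ["15"]


def test_tokenize_comment_only_and_empty():
    assert tokenize("// initialize user age") == []
    assert tokenize("") == []


def test_tokenize_brace_whitespace_trimmed():
    (tok,) = tokenize("{iVA_sleepRisk }")
    assert tok.kind == "varref" and tok.value == "iVA_sleepRisk"


@pytest.mark.parametrize("bad", ['"unterminated', "{unterminated"])
def test_tokenize_unterminated_raises_with_position(bad):
    with pytest.raises(LexError, match="offset"):
        tokenize(bad)


# --- parser ---------------------------------------------------------------

def test_parse_if_then_block():
    program = parse_logic(PTHX_STATUS_LOGIC)
    (stmt,) = program.statements
    assert isinstance(stmt, ast.If)
    assert isinstance(stmt.then, ast.Block)
    assert [s.target for s in stmt.then.statements] == ["ptHx_status",
                                                        "ptHx_done"]


def test_parse_nested_while_structure():
    program = parse_logic(NESTED_WHILE_LOGIC)
    outer_if = program.statements[1]
    assert isinstance(outer_if, ast.If)
    whiles = [s for s in outer_if.then.statements if isinstance(s, ast.While)]
    assert len(whiles) == 1
    assert any(isinstance(s, ast.If) for s in whiles[0].body.statements)


def test_parse_exit_trivial():
    assert parse_logic("exit;").statements == (ast.Exit(),)


@pytest.mark.parametrize("name,source", sorted(STATEMENT_SNIPPETS.items()))
def test_all_statement_catalogue_rows_parse(name, source):
    assert parse_logic(source).statements


def test_parse_call_as_rhs():
    (stmt,) = parse_logic(
        'set {age_m} = call calculateAgeInMonths("{ptHx_birthday}");'
    ).statements
    assert isinstance(stmt.expr, ast.CallExpr)
    assert stmt.expr.fn == "calculateAgeInMonths"


@pytest.mark.parametrize("bad", [
    'if ("{a}"=="1") set {b} = "2";',        # missing then
    'begin; set {a} = "1";',                 # unbalanced begin
])
def test_parse_errors(bad):
    with pytest.raises(LogicParseError):
        parse_logic(bad)


@pytest.mark.parametrize("source", [
    NESTED_WHILE_LOGIC, PTHX_STATUS_LOGIC, USERHX_VALIDATION_LOGIC,
    *STATEMENT_SNIPPETS.values(),
])
def test_unparse_is_fixed_point(source):
    once = parse_logic(source)
    assert parse_logic(unparse(once)) == once


# --- interpolation and coercion ------------------------------------------

def test_interpolate_examples(ctx):
    ctx.store.set("PCL_Q1", "3")
    ctx.store.set("ptHx_age", "15")
    assert interpolate("{PCL_Q1}", ctx.store) == "3"
    assert interpolate("age {ptHx_age} yrs", ctx.store) == "age 15 yrs"
    assert interpolate("no braces", ctx.store) == "no braces"


def test_undefined_variable_reads_empty(ctx):
    assert evaluate(ast.VarRef("nosuch_var"), ctx).raw == ""


@pytest.mark.parametrize("lhs,op,rhs,expected", [
    ("1", "<=", "2", True),
    ("10", "<", "9", False),      # numeric, though true lexically
    ("true", "==", "true", True),
    ("abc", "<", "abd", True),    # non-numeric falls back to text order
    ("50", ">", "50", False),
])
def test_coerce_compare(lhs, op, rhs, expected):
    assert coerce_compare(Value(lhs), op, Value(rhs)) is expected


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(a=st.decimals(allow_nan=False, allow_infinity=False, places=4),
       b=st.decimals(allow_nan=False, allow_infinity=False, places=4))
def test_coercion_agrees_with_decimal(a, b):
    """Numeric texts compare exactly as arbitrary-precision decimals."""
    assert coerce_compare(Value(str(a)), "<", Value(str(b))) == (a < b)
    assert coerce_compare(Value(str(a)), "==", Value(str(b))) == (a == b)


# --- evaluation -----------------------------------------------------------

def run(source, store=None, **ctx_kwargs):
    ctx = make_ctx(**ctx_kwargs)
    for k, v in (store or {}).items():
        ctx.store.set(k, v)
    execute(parse_logic(source), ctx)
    return ctx


def test_plus_is_numeric_when_both_numeric():
    ctx = run('set {PCL_Bcount} = "{PCL_Bcount}" + "1";',
              {"PCL_Bcount": "0"})
    assert ctx.store.get("PCL_Bcount") == "1"


def test_plus_concatenates_otherwise():
    ctx = run('set {t_x} = "x" + "y";')
    assert ctx.store.get("t_x") == "xy"


def test_minus_on_iso_dates_gives_days():
    ctx = run('set {t_d} = "{ptHx_today}" - "{ptHx_birthday}";',
              {"ptHx_today": "2024-03-10", "ptHx_birthday": "2024-03-03"})
    assert ctx.store.get("t_d") == "7"


def test_minus_on_text_raises_naming_operands():
    with pytest.raises(RuntimeLogicError, match="'abc'"):
        run('set {t_d} = "abc" - "1";')


def test_boolean_truth_table():
    for a, b, want in [("true", "false", "false"), ("true", "true", "true"),
                       ("false", "true", "false")]:
        ctx = run('set {t_r} = "{t_a}" && "{t_b}";', {"t_a": a, "t_b": b})
        assert ctx.store.get("t_r") == want
    ctx = run('set {t_r} = "{t_a}" || "{t_b}";',
              {"t_a": "false", "t_b": "true"})
    assert ctx.store.get("t_r") == "true"


def test_and_short_circuits():
    """The right operand of && is never evaluated when the left is false."""
    calls = []
    ctx = make_ctx()
    ctx.registry.register("probe", lambda c, a: (calls.append(1),
                                                 Value("true"))[1])
    execute(parse_logic(
        'if ("false" && call probe()) then set {t_x} = "1";'), ctx)
    assert calls == [] and ctx.store.get("t_x") is None
    execute(parse_logic(
        'if ("true" && call probe()) then set {t_y} = "1";'), ctx)
    assert calls == [1] and ctx.store.get("t_y") == "1"


def test_execute_nested_while_snippet():
    ctx = run(NESTED_WHILE_LOGIC, collection_id_source=lambda: "0")
    store = ctx.store
    assert store.get("iVA_i") == "3"
    assert store.get("iVA_another") == "foobar"
    assert store.get("randytest_zzzz") == "zzzz"
    assert store.get("randytest_abar") == ""
    assert store.get("iVA_alcoholStatus") == "monitoringScheduled"


def test_execute_status_transition():
    ctx = run(PTHX_STATUS_LOGIC, {"ptHx_status": "new"})
    assert ctx.store.get("ptHx_status") == "started"
    assert ctx.store.get("ptHx_done") == "false"


def test_execute_empty_program(ctx):
    signal = execute(parse_logic(""), ctx)
    assert signal.kind == "normal" and ctx.store.as_dict() == {}


def test_execute_is_deterministic():
    first = run(NESTED_WHILE_LOGIC, collection_id_source=lambda: "0")
    second = run(NESTED_WHILE_LOGIC, collection_id_source=lambda: "0")
    assert first.store.as_dict() == second.store.as_dict()


def test_while_guard_terminates():
    with pytest.raises(RuntimeLogicError, match="iterations"):
        run('set {t_i} = 0; while ({t_i} < 1) begin; '
            'set {t_j} = "1"; end;')


def test_control_signals_abort_program():
    ctx = run('set {t_a} = "1"; exit; set {t_b} = "2";')
    assert ctx.store.get("t_a") == "1"
    assert ctx.store.get("t_b") is None


# --- registry and built-ins ----------------------------------------------

def test_register_and_call_native_extension(ctx):
    ctx.registry.register("isPSQITrendingDownward",
                          lambda c, a: Value("true"))
    execute(parse_logic(
        'set {iVA_trend} = call isPSQITrendingDownward();'), ctx)
    assert ctx.store.get("iVA_trend") == "true"


def test_builtins_cannot_be_shadowed(ctx):
    with pytest.raises(ConfigError):
        ctx.registry.register("message", lambda c, a: Value(""))
    with pytest.raises(ConfigError):      # case-insensitive collision
        ctx.registry.register("Message", lambda c, a: Value(""))


def test_unregistered_function_raises(ctx):
    with pytest.raises(RuntimeLogicError, match="nosuch"):
        execute(parse_logic("call nosuch();"), ctx)


@pytest.mark.parametrize("value,decimals,expected", [
    ("171.6", "0", "172"),     # half-up
    ("171.4", "0", "171"),
    ("2.5", "0", "3"),         # half-up at the midpoint
    ("5", "2", "5.00"),
    ("0", "0", "0"),
])
def test_format_number(ctx, value, decimals, expected):
    ctx.store.set("t_v", value)
    execute(parse_logic(
        f'set {{t_r}} = call formatNumber({{t_v}}, {decimals});'), ctx)
    assert ctx.store.get("t_r") == expected


def test_format_number_rejects_text(ctx):
    with pytest.raises(RuntimeLogicError):
        execute(parse_logic('set {t_r} = call formatNumber("abc", 0);'), ctx)


def test_calculate_age_in_months():
    ctx = make_ctx(now=datetime(2024, 3, 10))
    execute(parse_logic(
        'set {t_m} = call calculateAgeInMonths("2024-01-09");'), ctx)
    assert ctx.store.get("t_m") == "2"
    execute(parse_logic(
        'set {t_f} = call calculateAgeInMonths("2024-04-01");'), ctx)
    assert Decimal(ctx.store.get("t_f")) < 0     # future birthday


def test_message_is_logged_not_displayed(ctx):
    execute(parse_logic('call message("User\'s birthday must be before '
                        'today.");'), ctx)
    assert ctx.messages == ["User's birthday must be before today."]


def test_generate_collection_id_is_monotonic(ctx):
    execute(parse_logic('set {t_a} = call generateCollectionId(); '
                        'set {t_b} = call generateCollectionId();'), ctx)
    assert int(ctx.store.get("t_b")) == int(ctx.store.get("t_a")) + 1


def test_capital_message_dispatches():
    ctx = run(STATEMENT_SNIPPETS["call"],
              {"ptHx_birthday": "1990-01-01", "iVA_height": "171.6"})
    assert ctx.store.get("iVA_height") == "172"
    assert ctx.messages == ["Patient birthday must be before today."]


def test_sleep_advisor_logic_runs_via_plain_execute():
    """The printed advisor script body is ordinary engine logic."""
    import xml.etree.ElementTree as ET
    source = ET.fromstring(SLEEP_ADVISOR_XML).find("assess/logic").text
    ctx = make_ctx(scheduler=make_scheduler())
    ctx.store.set("PSQI_complete", "true")
    ctx.store.set("PSQI_score", "17")
    execute(parse_logic(source), ctx)
    assert ctx.store.get("iVA_sleepRisk") == "3"
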