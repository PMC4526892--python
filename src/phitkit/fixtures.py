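"""Bundled fixtures: the worked XML examples plus generated stand-ins.

The single-form PCL excerpt, the multi-entity family form, the
patient-history logic snippets, and the sleep assessment/plan advisor
reproduce the published worked examples of the instrument dialect.  The
full-length screeners (17-item PCL-style, 19-item PSQI-style) are
*synthetic structural stand-ins*: same variable names, item counts,
codebooks, and score ranges as the standardized instruments they
emulate, but generic prompt text — the real instruments are
copyrighted and are not reproduced.

Everything here is plain text generated in memory; ``write_fixture_app``
materializes a complete two-protocol study bundle into a directory for
end-to-end runs.
"""
from __future__ import annotations

from pathlib import Path

# --- single-form PCL excerpt (worked example) -----------------------------

PCL_FORM1_XML = """\
<instrument name="PCL" title="PTSD Checklist" kind="interactive" menuIndex="1">
  <form name="F1">
    <entity name="Q1" type="radio" required="true">
      <text>
        To what extent are you bothered by repeated, disturbing
        memories, thoughts, or images of a stressful experience
        from the past?
      </text>
      <item code="1">Not at all</item>
      <item code="2">A little bit</item>
      <item code="3">Moderately</item>
      <item code="4">Quite a bit</item>
      <item code="5">Extremely</item>
    </entity>
    <logic event="onFormExit"><![CDATA[
      if ("{PCL_Q1}">="3") then
        set {PCL_Bcount} = "{PCL_Bcount}" + "1";
    ]]></logic>
  </form>
</instrument>
"""

# --- multi-entity family form (worked example, layout containers) ---------

FAMILY_FORM_XML = """\
<instrument name="family" title="Family" kind="interactive" menuIndex="2">
  <form name="f2" title="Multiple Entities">
    <vertical styleName="layoutVGroup1">
      <text name="sometextname" save="true" styleName="layoutTextLabel">
        Tell us about your family</text>
      <text styleName="layoutTextLabel2">First the adults</text>
      <horizontal styleName="layoutHGroup100Percent">
        <entity name="mom" layout="itemHorizontal" type="radio"
                styleName="radioWidget" required="true">
          <text>Mom</text>
          <item code="yes">Yes</item>
          <item code="no">No</item>
        </entity>
        <entity name="dad" type="radio">
          <text>Dad</text>
          <item code="yes">Yes (showing word wrap)</item>
          <item code="no">No</item>
        </entity>
      </horizontal>
      <text styleName="layoutTextLabel2">And about those siblings</text>
      <entity name="sib" layout="fullHorizontal" type="radio">
        <text>Do you have any?</text>
        <item code="Y">Yes</item>
        <item code="N">No</item>
      </entity>
      <entity name="numSibs" layout="itemHorizontal" type="text">
        <text>How many?</text>
      </entity>
    </vertical>
  </form>
</instrument>
"""

# --- patient/user-history logic snippets (worked examples) ----------------

USERHX_VALIDATION_LOGIC = """\
set {userHx_ageMonths} = "-1"; // initialize user age
if ("{userHx_userID}" == "" && "{userHx_userID_YN}" == "not asked") then
  call message("Are you sure you don't wish to personalize the application instrument? If so, hit Next again.");
if ("{userHx_ageMonths}" < "0") then
begin;
  call message("User's birthday must be before today.");
  goto F1_Birthday;
end;
"""

PTHX_STATUS_LOGIC = """\
if ("{ptHx_status}"=="new") then
  begin;
    set {ptHx_status} = "started";
    set {ptHx_done} = "false";
  end;
"""

PTHX_XML = """\
<instrument name="ptHx" title="Patient History" kind="interactive" menuIndex="3">
  <logic event="onInstrumentEnter"><![CDATA[
    if ("{ptHx_status}"=="new") then
      begin;
        set {ptHx_status} = "started";
        set {ptHx_done} = "false";
      end;
  ]]></logic>
  <form name="F0_PtID">
    <entity name="ptID" type="text">
      <text>Participant identifier</text>
    </entity>
  </form>
  <form name="F1_Birthday">
    <entity name="birthday" type="date">
      <text>Date of birth</text>
    </entity>
    <logic event="onValidate"><![CDATA[
      set {ptHx_ageMonths} = call calculateAgeInMonths("{ptHx_birthday}");
      if ("{ptHx_ageMonths}" < "0") then
      begin;
        call message("User's birthday must be before today.");
        goto F1_Birthday;
      end;
    ]]></logic>
  </form>
  <logic event="onInstrumentExit"><![CDATA[
    set {ptHx_done} = "true";
  ]]></logic>
</instrument>
"""

# --- statement-catalogue snippets (worked examples) -----------------------

NESTED_WHILE_LOGIC = """\
set {randytest_collectId1} = call generateCollectionId();
if ("{randytest_collectId1}">="0") then begin;
  set {iVA_alcoholInstr} = "CAGE";
  set {iVA_alcoholInstrWording} = "past two weeks";
  if ("{randytest_collectId1}" == "0") then begin;
    set {iVA_another} = "foobar";
  end;
  set {iVA_alcoholOnQueue} = "foobar";
  set {iVA_alcoholStatus} = "monitoringScheduled";
  set {iVA_i} = 0;
  while ({iVA_i} < 3) begin;
    set {iVA_i} = {iVA_i} + 1;
    if ("{iVA_i}" == "1") then set {randytest_zzzz} = "zzzz";
  end;
end;
set {randytest_collectId2} = call generateCollectionId();
var {randytest_abar} = "";
"""

STATEMENT_SNIPPETS = {
    "set": 'set {ptHx_age} = “15”;set {ptHX_gender} = “M”;',
    "call": ('set {age_m} = call calculateAgeInMonths("{ptHx_birthday}");'
             'call Message("Patient birthday must be before today.");'
             'set {iVA_height}=call formatNumber({iVA_height}, 0);'),
    "conditional": ('if ("{ptHx_ageMonths}">="0" && "{ptHx_ageMonths}"<="48"'
                    ' && "{iVA_isExposed}")'
                    'then set {iVA_tobaccoCode}="Under4Exposure";'),
    "skip": 'if ("{ptHx_ptID}"=="") then goto F0_PtID;',
    "exit": 'exit;',
    "nextform": ('if (("{ptHx_today}"-"{ptHx_birthday}")<"{ptHx_one_week}") '
                 'then nextForm;'),
    "nested": NESTED_WHILE_LOGIC,
    "block": ('begin; set {ptHx_status} = "started"; '
              'set {ptHx_done} = "false";end;'),
}

# --- sleep advisor (worked example) ---------------------------------------

SLEEP_ADVISOR_XML = """\
<advisor>
  <assess domain="sleep">
    <logic><![CDATA[
      // Assess the sleep risk
      if ("{PSQI_complete}" == "true") then begin;
        set {iVA_sleepIntervene} = "false";
        if ("{PSQI_score}"<="7") then set {iVA_sleepRisk} = "1";
        if ("{PSQI_score}">="8" && "{PSQI_score}"<="15") then
          set {iVA_sleepRisk} = "2";
        if ("{PSQI_score}">="16" && "{PSQI_score}"<="19") then
          set {iVA_sleepRisk} = "3";
        if ("{PSQI_score}">="20") then set {iVA_sleepRisk} = "4";
        if ("{iVA_sleepRisk}">"1") then set {iVA_sleepIntervene} = "true";
        set {iVA_scheduleSleep} = "true";
      end;
      if ("{iVA_sleepRisk }" >= "3") then begin;
        // Plan the sleep self-help intervention
        // List the sleep environment and mindfulness meditation tasks
        call scheduleTask("sleep%environment");
        call scheduleTask("mindfulness%bodyScan");
        // Reschedule the PSQI assessment according to protocol
        call scheduleTask("PSQI", "P1DTA8H", null, "FREQ=DAILY,INTERVAL=3");
      end;
    ]]></logic>
  </assess>
</advisor>
"""

# --- risk-alert rules (thresholds from the published intervention list) ---

RISK_ALERTS_XML = """\
<advisor>
  <alert domain="post-traumatic stress" score="PCLM_score" threshold="50"
         message="PCL-M score exceeds 50: advise professional evaluation"/>
  <alert domain="sleep quality" score="PSQI_score" threshold="22"
         message="PSQI score exceeds 22: advise professional evaluation"/>
  <alert domain="alcohol" score="AUDIT_score" threshold="20"
         message="AUDIT score exceeds 20: advise professional evaluation"/>
  <alert domain="anxiety" score="GAD7_score" threshold="15"
         message="GAD-7 score exceeds 15: advise professional evaluation"/>
  <alert domain="depression" score="PHQ8_score" threshold="10"
         message="PHQ-8 score exceeds 10: advise professional evaluation"/>
</advisor>
"""

# --- background (script) instrument ---------------------------------------

BATTERY_SCRIPT_XML = """\
<instrument name="battery" title="Battery check" kind="script" menuIndex="9">
  <logic event="onInstrumentEnter"><![CDATA[
    set {battery_level} = "{sys_batteryLevel}";
    call saveValue("battery_level", "{battery_level}");
  ]]></logic>
</instrument>
"""

EMPTY_SCRIPT_XML = """\
<instrument name="noop" kind="script" menuIndex="8"/>
"""

# --- generated full-length stand-ins --------------------------------------

PCL_ITEM_COUNT = 17
PCL_LABELS = ["Not at all", "A little bit", "Moderately",
              "Quite a bit", "Extremely"]


def pcl17_xml() -> str:
    """17-item PCL-style instrument: one radio item per form, five-point
    response scale, every form's exit logic counting answers >= 3."""
    forms = []
    for n in range(1, PCL_ITEM_COUNT + 1):
        items = "\n".join(
            f'      <item code="{c}">{label}</item>'
            for c, label in enumerate(PCL_LABELS, start=1))
        forms.append(f"""\
  <form name="F{n}">
    <entity name="Q{n}" type="radio" required="true">
      <text>Stress symptom item {n} (structural stand-in)</text>
{items}
    </entity>
    <logic event="onFormExit"><![CDATA[
      if ("{{PCL_Q{n}}}">="3") then
        set {{PCL_Bcount}} = "{{PCL_Bcount}}" + "1";
    ]]></logic>
  </form>""")
    body = "\n".join(forms)
    return (f'<instrument name="PCL" title="PTSD Checklist" '
            f'kind="interactive" menuIndex="1">\n'
            f'  <logic event="onInstrumentEnter"><![CDATA[\n'
            f'    set {{PCL_Bcount}} = "0";\n'
            f'  ]]></logic>\n'
            f'{body}\n'
            f'  <logic event="onInstrumentExit"><![CDATA[\n'
            f'    set {{PCL_complete}} = "true";\n'
            f'    call saveValue("PCL_Bcount", "{{PCL_Bcount}}");\n'
            f'  ]]></logic>\n'
            f'</instrument>\n')


PSQI_ITEM_COUNT = 19


def psqi_xml() -> str:
    """19-item PSQI-style instrument.  The global score is the sum of the
    first seven items (component stand-ins, each 0-3), giving the real
    instrument's 0-21 score range."""
    entities = []
    for n in range(1, PSQI_ITEM_COUNT + 1):
        items = "\n".join(f'      <item code="{c}">Level {c}</item>'
                          for c in range(0, 4))
        entities.append(f"""\
    <entity name="Q{n}" type="likert" required="true">
      <text>Sleep quality item {n} (structural stand-in)</text>
{items}
    </entity>""")
    # four forms of 5/5/5/4 items, mirroring a multi-screen layout
    chunks = [entities[0:5], entities[5:10], entities[10:15], entities[15:]]
    forms = []
    for i, chunk in enumerate(chunks, start=1):
        forms.append(f'  <form name="S{i}">\n' + "\n".join(chunk) +
                     "\n  </form>")
    score_terms = "\n".join(
        f'    set {{PSQI_score}} = "{{PSQI_score}}" + "{{PSQI_Q{n}}}";'
        for n in range(1, 8))
    return (f'<instrument name="PSQI" title="Sleep Quality Index" '
            f'kind="interactive" menuIndex="2">\n'
            f'{chr(10).join(forms)}\n'
            f'  <logic event="onInstrumentExit"><![CDATA[\n'
            f'    set {{PSQI_score}} = "0";\n'
            f'{score_terms}\n'
            f'    set {{PSQI_complete}} = "true";\n'
            f'    call saveValue("PSQI_score", "{{PSQI_score}}");\n'
            f'    call saveValue("PSQI_complete", "true");\n'
            f'  ]]></logic>\n'
            f'</instrument>\n')


def intervention_xml(name: str, title: str, sections: list[str],
                     menu_index: int = 5) -> str:
    """Minimal slide-show intervention: one image-display form per
    section (media entities just record a "presented" event headlessly)."""
    forms = []
    for section in sections:
        forms.append(f"""\
  <form name="{section}">
    <entity name="{section}Slide" type="imageDisplay" save="false">
      <text>{title}: {section}</text>
    </entity>
  </form>""")
    return (f'<instrument name="{name}" title="{title}" kind="interactive" '
            f'menuIndex="{menu_index}">\n' + "\n".join(forms) +
            '\n</instrument>\n')


APP_CONFIG_XML = """\
<app project="demo">
  <study id="S1">
    <protocol id="A">
      <instrument taskId="PCL" file="pcl.xml" menuIndex="1"/>
      <instrument taskId="PSQI" file="psqi.xml" menuIndex="2"/>
      <instrument taskId="ptHx" file="pthx.xml" menuIndex="3"/>
      <advisor file="advisor.xml"/>
      <intervention taskId="sleep%environment" file="sleep.xml"
                    section="environment" menuIndex="5"
                    title="Improving your sleep"/>
      <intervention taskId="mindfulness%bodyScan" file="mindfulness.xml"
                    section="bodyScan" menuIndex="6"
                    title="Body scan meditation"/>
    </protocol>
    <protocol id="B">
      <instrument taskId="PCL" file="pcl.xml" menuIndex="1"/>
      <instrument taskId="PSQI" file="psqi.xml" menuIndex="2"/>
    </protocol>
  </study>
</app>
"""


def combined_advisor_xml() -> str:
    """Sleep assess/plan blocks plus the risk-alert rule set in one file."""
    import xml.etree.ElementTree as ET
    root = ET.fromstring(SLEEP_ADVISOR_XML)
    for alert in ET.fromstring(RISK_ALERTS_XML):
        root.append(alert)
    # re-serialize loses CDATA wrapping but keeps the logic text intact
    return ET.tostring(root, encoding="unicode")


def write_fixture_app(directory: str | Path) -> Path:
    """Materialize the demo study bundle (app.xml + referenced files);
    returns the path to app.xml."""
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    (base / "pcl.xml").write_text(pcl17_xml())
    (base / "psqi.xml").write_text(psqi_xml())
    (base / "pthx.xml").write_text(PTHX_XML)
    (base / "advisor.xml").write_text(combined_advisor_xml())
    (base / "sleep.xml").write_text(intervention_xml(
        "sleep", "Improving your sleep",
        ["environment", "preparing", "bedroom"], menu_index=5))
    (base / "mindfulness.xml").write_text(intervention_xml(
        "mindfulness", "Body scan meditation",
        ["bodyScan", "sitting"], menu_index=6))
    app_path = base / "app.xml"
    app_path.write_text(APP_CONFIG_XML)
    return app_path
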