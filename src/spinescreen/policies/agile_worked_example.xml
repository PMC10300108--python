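<?xml version='1.0' encoding='UTF-8'?>
<PolicySuite name="SpineScreening">
  <EnvironmentVariables>
    <Variable name="Amplitude" kind="number"/>
    <Variable name="Width" kind="number"/>
  </EnvironmentVariables>
  <InternalVariables>
    <Variable name="RefAmplitude" kind="number" default="0"/>
    <Variable name="RefWidth" kind="number" default="0"/>
  </InternalVariables>
  <ReturnValues>
    <ReturnValue name="SpineOK"/>
    <ReturnValue name="SpineNOK"/>
  </ReturnValues>
  <Template name="SpineThresholds">
    <Assign var="RefAmplitude" value="2"/>
    <Assign var="RefWidth" value="100"/>
  </Template>
  <ToleranceRangeCheck name="TRC1" monitored="Amplitude" reference="RefAmplitude" tolerance="0.5" onInZone="ActionCheckWidth" onBelow="ActionSpineNOK" onAbove="ActionSpineNOK"/>
  <ToleranceRangeCheck name="TRC2" monitored="Width" reference="RefWidth" tolerance="10" onInZone="ActionSpineOK" onBelow="ActionSpineNOK" onAbove="ActionSpineNOK"/>
  <Action name="ActionCheckAmplitude">
    <Evaluate ref="TRC1"/>
  </Action>
  <Action name="ActionCheckWidth">
    <Evaluate ref="TRC2"/>
  </Action>
  <Action name="ActionSpineOK">
    <Return value="SpineOK"/>
  </Action>
  <Action name="ActionSpineNOK">
    <Return value="SpineNOK"/>
  </Action>
  <Policy name="SpineScreeningPolicy" entry="ActionCheckAmplitude">
    <LoadTemplate ref="SpineThresholds"/>
  </Policy>
</PolicySuite>
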