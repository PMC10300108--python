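<?xml version='1.0' encoding='UTF-8'?>
<FuzzyPolicy name="SpineScreeningFuzzy" output="Condition">
  <LinguisticVariables>
    <LinguisticVariable name="LAmpl" role="input">
      <Universe lo="0" hi="4"/>
      <MembershipFunctions>
        <MF Name="Small" Type="Trapezoid" Value="0,0,0.6,1.4"/>
        <MF Name="Medium" Type="Trapezoid" Value="0.6,1.4,2.2,3"/>
        <MF Name="High" Type="Trapezoid" Value="2.2,3,4,4"/>
      </MembershipFunctions>
    </LinguisticVariable>
    <LinguisticVariable name="LWdth" role="input">
      <Universe lo="0" hi="400"/>
      <MembershipFunctions>
        <MF Name="Small" Type="Trapezoid" Value="0,0,80,160"/>
        <MF Name="Medium" Type="Trapezoid" Value="80,160,240,320"/>
        <MF Name="High" Type="Trapezoid" Value="240,320,400,400"/>
      </MembershipFunctions>
    </LinguisticVariable>
    <LinguisticVariable name="LCond" role="output">
      <Universe lo="0" hi="1"/>
      <MembershipFunctions>
        <MF Name="Small" Type="Trapezoid" Value="0,0,0.25,0.45"/>
        <MF Name="Medium" Type="Trapezoid" Value="0.25,0.45,0.55,0.75"/>
        <MF Name="High" Type="Trapezoid" Value="0.55,0.75,1,1"/>
      </MembershipFunctions>
    </LinguisticVariable>
  </LinguisticVariables>
  <LVar context="Amplitude" linguistic="LAmpl" direction="fuzzify"/>
  <LVar context="Width" linguistic="LWdth" direction="fuzzify"/>
  <LVar context="Condition" linguistic="LCond" direction="defuzzify"/>
  <FuzzyRules>
    <FuzzyRule>
      <If lvar="LAmpl" term="Small"/>
      <If lvar="LWdth" term="Small"/>
      <Then lvar="LCond" term="Medium"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="Medium"/>
      <If lvar="LWdth" term="Small"/>
      <Then lvar="LCond" term="Small"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="High"/>
      <If lvar="LWdth" term="Small"/>
      <Then lvar="LCond" term="Small"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="Small"/>
      <If lvar="LWdth" term="Medium"/>
      <Then lvar="LCond" term="High"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="Medium"/>
      <If lvar="LWdth" term="Medium"/>
      <Then lvar="LCond" term="Medium"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="High"/>
      <If lvar="LWdth" term="Medium"/>
      <Then lvar="LCond" term="Small"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="Small"/>
      <If lvar="LWdth" term="High"/>
      <Then lvar="LCond" term="High"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="Medium"/>
      <If lvar="LWdth" term="High"/>
      <Then lvar="LCond" term="High"/>
    </FuzzyRule>
    <FuzzyRule>
      <If lvar="LAmpl" term="High"/>
      <If lvar="LWdth" term="High"/>
      <Then lvar="LCond" term="Medium"/>
    </FuzzyRule>
  </FuzzyRules>
</FuzzyPolicy>
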