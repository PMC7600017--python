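<?xml version='1.0' encoding='UTF-8'?>
<!--
Bacteriuria treatment choice: goal is a patient free of bacteria in the
urine; a urine-culture CFU count strictly over 100,000 triggers a first-line
antibiotic order, and the (10,000; 100,000] band (a fixture configuration
choice, not a normative threshold) triggers an alternative-treatment
recommendation plus a physician alert.
-->
<guideline xmlns="urn:cigx:1" id="bacteriuria_example" title="Bacteriuria treatment choice" version="1.0">
  <node id="bacteriuria" label="Bacteriuria treatment">
    <goal>
      <description>Patient free of bacteria in the urine</description>
      <conditions>
        <eq>
          <symbol path="labs/urine_culture/bacteria_present"/>
          <value type="boolean">false</value>
        </eq>
      </conditions>
    </goal>
    <rule id="high_cfu">
      <precondition trigger="diagnostic_test_value">
        <gt>
          <symbol path="labs/urine_culture/cfu"/>
          <value type="integer">100000</value>
        </gt>
      </precondition>
      <action kind="medication_order">
        <payload>first-line antibiotic course (empiric, per local antibiogram)</payload>
      </action>
    </rule>
    <rule id="low_cfu">
      <precondition trigger="diagnostic_test_value">
        <and>
          <gt>
            <symbol path="labs/urine_culture/cfu"/>
            <value type="integer">10000</value>
          </gt>
          <le>
            <symbol path="labs/urine_culture/cfu"/>
            <value type="integer">100000</value>
          </le>
        </and>
      </precondition>
      <action kind="recommendation">
        <payload>alternative treatment matched to patient condition at lower colony count</payload>
      </action>
      <action kind="alert">
        <payload>notify physician: bacteriuria persists at lower CFU</payload>
      </action>
    </rule>
  </node>
</guideline>
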