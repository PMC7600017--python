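<?xml version='1.0' encoding='UTF-8'?>
<!--
Deliberately pathological document: two calculations flip one flag back
and forth forever, demonstrating the engine's cycle limit.
-->
<guideline xmlns="urn:cigx:1" id="cyclic_example" title="Cycle-limit demonstration" version="1.0">
  <node id="cyclic" label="Deliberately non-quiescent rule set">
    <goal>
      <description>never satisfied</description>
      <conditions>
        <false/>
      </conditions>
    </goal>
    <rule id="flip_on">
      <precondition trigger="clinical_data_pattern">
        <eq>
          <symbol path="sim/flag"/>
          <value type="boolean">false</value>
        </eq>
      </precondition>
      <action kind="calculation">
        <payload>set flag</payload>
        <assign path="sim/flag" type="boolean" value="true"/>
      </action>
    </rule>
    <rule id="flip_off">
      <precondition trigger="clinical_data_pattern">
        <eq>
          <symbol path="sim/flag"/>
          <value type="boolean">true</value>
        </eq>
      </precondition>
      <action kind="calculation">
        <payload>clear flag</payload>
        <assign path="sim/flag" type="boolean" value="false"/>
      </action>
    </rule>
  </node>
</guideline>
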